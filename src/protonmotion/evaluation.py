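"""Per-phase and 4-D plan evaluation.

The motion robustness of a plan is judged by recomputing its dose on each
respiratory phase CT with every piece of beam hardware frozen (ranges,
SOBP weights, apertures, compensators, weights and the plan normalization
factor), extracting target dose indices, and comparing them with the
plan's own apparent 3-D values: a plan is acceptable at a phase if all of
D95%, D99% and D100% change by at most 2 percentage points of
prescription (inclusive).  The 4-D dose is the equal-weighted voxel-wise
composition of the ten per-phase doses overlaid rigidly on the common
grid (the AVG volume's grid), judged by the same +/-2% rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_ops import CalibrationCurve, hu_to_rsp
from .dose_engine import compute_plan_dose
from .errors import GeometryError, UndefinedCIError
from .phantom import PhaseSeries
from .planning import Plan
from .volumes import DoseVolume, HUVolume

ACCEPTABILITY_TOL = 2.0  # percentage points of prescription, inclusive
INDEX_NAMES = ("D95", "D99", "D100")


@dataclass
class DoseIndices:
    """Minimal doses covering 95/99/100% of the target, plus conformity."""

    d95: float
    d99: float
    d100: float
    ci: float | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d95, self.d99, self.d100)


def recompute_on_phase(
    plan: Plan, phase: HUVolume, calibration: CalibrationCurve | None = None
) -> DoseVolume:
    """Recompute the plan dose on one phase CT with frozen hardware."""
    plan.planning_volume.require_same_grid(phase)
    rsp = hu_to_rsp(phase, calibration)
    raw = compute_plan_dose(plan.fields, rsp)
    return raw.with_values(raw.values * plan.normalization_factor)


def dose_index(dose: DoseVolume, mask: np.ndarray, x: float) -> float:
    """Dx%: the largest dose received by at least x% of the masked voxels.

    Sort-based order statistic with linear interpolation between order
    statistics at non-integer ranks; D100% is the structure minimum.
    """
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    vals = dose.values[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise GeometryError("empty structure mask")
    srt = np.sort(vals)
    rank = (1.0 - x / 100.0) * srt.size
    return float(np.interp(rank, np.arange(srt.size), srt))


def compute_indices(
    dose: DoseVolume, mask: np.ndarray, ci_level: float = 95.0
) -> DoseIndices:
    return DoseIndices(
        d95=dose_index(dose, mask, 95),
        d99=dose_index(dose, mask, 99),
        d100=dose_index(dose, mask, 100),
        ci=conformity_index(dose, mask, ci_level),
    )


def conformity_index(
    dose: DoseVolume, ptv_mask: np.ndarray, level: float = 95.0
) -> float:
    """Total volume at or above ``level`` over target volume at or above it."""
    covered = dose.values >= level
    target_covered = int(np.count_nonzero(covered & np.asarray(ptv_mask, bool)))
    if target_covered == 0:
        raise UndefinedCIError(f"no target voxel receives >= {level}%")
    return float(np.count_nonzero(covered)) / target_covered


def compose_4d(
    phase_doses: list[DoseVolume], weights: np.ndarray | None = None
) -> DoseVolume:
    """Weighted voxel-wise mean of per-phase doses on the common grid."""
    if not phase_doses:
        raise GeometryError("no phase doses")
    ref = phase_doses[0]
    for d in phase_doses[1:]:
        ref.require_same_grid(d)
    if weights is None:
        weights = np.full(len(phase_doses), 1.0 / len(phase_doses))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(phase_doses):
        raise ValueError("one weight per phase required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("phase weights must sum to 1")
    total = sum(w * d.values for w, d in zip(weights, phase_doses))
    return ref.with_values(total)


def dvh(dose: DoseVolume, mask: np.ndarray, step: float = 0.5):
    """Cumulative dose-volume histogram: fraction of the structure at or
    above each dose level, starting at 1.0 for level 0."""
    vals = dose.values[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise GeometryError("empty structure mask")
    levels = np.arange(0.0, vals.max() + 2 * step, step)
    frac = np.array([(vals >= lv).mean() for lv in levels])
    return levels, frac


@dataclass
class PhaseResult:
    label: int | str
    indices: DoseIndices
    deltas: tuple[float, float, float]  # (dD95, dD99, dD100) vs 3-D baseline
    passed: bool

    @property
    def worst_delta(self) -> float:
        return max(abs(d) for d in self.deltas)


@dataclass
class PhaseReport:
    """Acceptability verdicts for every phase and for the 4-D composite."""

    strategy: str
    baseline: DoseIndices
    phases: list[PhaseResult]
    composite: PhaseResult
    tolerance: float = ACCEPTABILITY_TOL

    @property
    def all_phases_pass(self) -> bool:
        return all(p.passed for p in self.phases)

    def phase(self, label) -> PhaseResult:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    def worst_phase(self) -> PhaseResult:
        return max(self.phases, key=lambda p: p.worst_delta)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in [*self.phases, self.composite]:
            rows.append(
                {
                    "strategy": self.strategy,
                    "phase": p.label,
                    "D95": p.indices.d95,
                    "D99": p.indices.d99,
                    "D100": p.indices.d100,
                    "CI": p.indices.ci,
                    "dD95": p.deltas[0],
                    "dD99": p.deltas[1],
                    "dD100": p.deltas[2],
                    "pass": p.passed,
                }
            )
        return pd.DataFrame(rows)


def _result(label, indices, baseline, tolerance) -> PhaseResult:
    deltas = tuple(
        v - b for v, b in zip(indices.as_tuple(), baseline.as_tuple())
    )
    passed = all(abs(d) <= tolerance + 1e-12 for d in deltas)
    return PhaseResult(label=label, indices=indices, deltas=deltas, passed=passed)


def acceptability_report(
    plan: Plan,
    series: PhaseSeries,
    calibration: CalibrationCurve | None = None,
    tolerance: float = ACCEPTABILITY_TOL,
    return_doses: bool = False,
):
    """Recompute on every phase, compose the 4-D dose, and apply the
    +/- ``tolerance`` rule to each phase and to the composite."""
    ptv = plan.structures.ptv
    baseline = compute_indices(plan.dose, ptv)
    phase_results = []
    phase_doses = []
    for lbl, phase in zip(series.labels, series.phases):
        d = recompute_on_phase(plan, phase, calibration)
        phase_doses.append(d)
        phase_results.append(_result(lbl, compute_indices(d, ptv), baseline, tolerance))
    composite_dose = compose_4d(phase_doses, series.phase_weights)
    composite = _result(
        "4D", compute_indices(composite_dose, ptv), baseline, tolerance
    )
    report = PhaseReport(
        strategy=plan.strategy,
        baseline=baseline,
        phases=phase_results,
        composite=composite,
        tolerance=tolerance,
    )
    if return_doses:
        return report, phase_doses, composite_dose
    return report
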