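"""The four motion-compensation planning strategies.

AVG, MIP and OVR plans are ordinary 3-D plans built on the corresponding
derived CT volume with two (by default) equally weighted orthogonal
coplanar fields, each fitted to the PTV and normalized so the minimum PTV
dose is exactly 95% of prescription (100% coverage at the 95% isodose).
The mAVG plan is the AVG plan with a field-specific distal proton margin:
each field's range and SOBP width grow by that field's MIP-minus-AVG range
difference, so the proximal 90% depth is preserved (the AVG plan's proximal
coverage) while the distal 90% depth matches the MIP plan's.  Compensators,
apertures, angles and weights are inherited unchanged, and the plan dose is
recomputed on the AVG volume and re-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import ct_ops
from .beam_model import build_sobp
from .ct_ops import CalibrationCurve, StructureSet, hu_to_rsp
from .dose_engine import BeamGeometry, BeamField, compute_plan_dose, fit_field
from .errors import GeometryError, NormalizationError
from .phantom import PhaseSeries
from .volumes import DoseVolume, HUVolume

STRATEGIES = ("AVG", "MIP", "OVR", "mAVG")
DEFAULT_ANGLES = (180, 270)  # posterior + right lateral, clockwise order
COVERAGE_LEVEL = 95.0  # % of prescription covering 100% of the PTV


@dataclass
class FieldMargins:
    """Per-field distal range increments (cm WEPL), MIP minus AVG."""

    delta_r_cm: np.ndarray

    def __post_init__(self):
        self.delta_r_cm = np.atleast_1d(np.asarray(self.delta_r_cm, dtype=float))

    @property
    def any_negative(self) -> bool:
        return bool(np.any(self.delta_r_cm < 0))


@dataclass
class Plan:
    """A complete plan: strategy, planning volume, fields, normalized dose."""

    strategy: str
    planning_volume: HUVolume
    fields: list[BeamField]
    structures: StructureSet
    dose: DoseVolume  # normalized apparent (3-D) dose, % of prescription
    normalization_factor: float
    margins: FieldMargins | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.fields:
            raise GeometryError("plan needs at least one field")
        if self.normalization_factor <= 0:
            raise ValueError("normalization factor must be positive")

    @property
    def angles(self) -> tuple[float, ...]:
        return tuple(f.geometry.gantry_angle for f in self.fields)

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "normalization_factor": round(self.normalization_factor, 6),
            "ptv_margin_mm": self.structures.ptv_margin_mm,
            "fields": [f.summary() for f in self.fields],
        }


def normalize_to_coverage(
    dose: DoseVolume, ptv_mask: np.ndarray, level: float = COVERAGE_LEVEL
) -> tuple[DoseVolume, float]:
    """Scale so the minimum PTV dose equals ``level`` % of prescription."""
    if not np.any(ptv_mask):
        raise GeometryError("empty PTV")
    dmin = float(dose.values[ptv_mask.astype(bool)].min())
    if dmin <= 0:
        raise NormalizationError("a PTV voxel receives zero dose")
    factor = level / dmin
    return dose.with_values(dose.values * factor), factor


def planning_volume(
    strategy: str, series: PhaseSeries, structures: StructureSet
) -> HUVolume:
    """The derived CT volume each strategy plans on."""
    avg = ct_ops.average_ct(series)
    if strategy in ("AVG", "mAVG"):
        return avg
    if strategy == "MIP":
        return ct_ops.mip_ct(series)
    if strategy == "OVR":
        return ct_ops.override_ptv_density(avg, structures.ptv, structures.itv)
    raise ValueError(f"unknown strategy {strategy!r}")


def build_plan(
    strategy: str,
    series: PhaseSeries,
    structures: StructureSet,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
    calibration: CalibrationCurve | None = None,
) -> Plan:
    """Design and normalize a 3-D plan on the strategy's planning volume.

    ``mAVG`` cannot be built directly; derive it from the AVG and MIP plans
    with :func:`field_specific_margins` and :func:`apply_margins`.
    """
    if strategy == "mAVG":
        raise ValueError("build mAVG via apply_margins(avg_plan, margins)")
    vol = planning_volume(strategy, series, structures)
    rsp = hu_to_rsp(vol, calibration)
    weight = 1.0 / len(angles)
    fields = [
        fit_field(structures.ptv, rsp, BeamGeometry(a), weight=weight) for a in angles
    ]
    raw = compute_plan_dose(fields, rsp)
    dose, factor = normalize_to_coverage(raw, structures.ptv)
    return Plan(
        strategy=strategy,
        planning_volume=vol,
        fields=fields,
        structures=structures,
        dose=dose,
        normalization_factor=factor,
    )


def field_specific_margins(avg_plan: Plan, mip_plan: Plan) -> FieldMargins:
    """Distal range differences (MIP - AVG) per field, in field order."""
    if avg_plan.angles != mip_plan.angles:
        raise GeometryError(
            f"field sets differ: {avg_plan.angles} vs {mip_plan.angles}"
        )
    deltas = [
        m.distal_range_cm - a.distal_range_cm
        for a, m in zip(avg_plan.fields, mip_plan.fields)
    ]
    return FieldMargins(np.array(deltas))


def apply_margins(
    avg_plan: Plan,
    margins: FieldMargins,
    calibration: CalibrationCurve | None = None,
) -> Plan:
    """Build the mAVG plan: widen each AVG field's SOBP distally by its margin.

    Per field, R -> R + dR and M -> M + dR, which keeps the proximal 90%
    depth fixed while moving the distal 90% depth to the MIP plan's; all
    other hardware (compensator, aperture, angles, weights) is inherited
    unchanged.  The dose is recomputed on the AVG volume and re-normalized.
    """
    if len(margins.delta_r_cm) != len(avg_plan.fields):
        raise GeometryError("one margin per field is required")
    new_fields = []
    for f, dr in zip(avg_plan.fields, margins.delta_r_cm):
        dr = float(dr)
        if dr == 0.0:
            nf = replace(f, distal_margin_cm=0.0)
        else:
            R = f.distal_range_cm + dr
            M = f.modulation_cm + dr
            spec, curve = build_sobp(R, M)
            nf = replace(
                f,
                distal_range_cm=R,
                modulation_cm=M,
                sobp_spec=spec,
                sobp_curve=curve,
                distal_margin_cm=dr,
            )
        new_fields.append(nf)
    rsp = hu_to_rsp(avg_plan.planning_volume, calibration)
    raw = compute_plan_dose(new_fields, rsp)
    dose, factor = normalize_to_coverage(raw, avg_plan.structures.ptv)
    return Plan(
        strategy="mAVG",
        planning_volume=avg_plan.planning_volume,
        fields=new_fields,
        structures=avg_plan.structures,
        dose=dose,
        normalization_factor=factor,
        margins=margins,
    )
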