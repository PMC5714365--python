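"""Derived CT volumes, target structures, and HU-to-stopping-power conversion.

From a 4D phase series this module builds the three planning volumes used by
the compared strategies -- the per-voxel mean (AVG), the per-voxel maximum
(MIP), and the AVG volume with the planning target overridden to the mean
gross-tumor HU (OVR) -- together with the GTV -> ITV -> PTV structure chain,
and converts any HU volume into relative proton stopping power via a
piecewise-linear calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, GeometryError
from .phantom import PhaseSeries
from .volumes import HUVolume, RSPVolume


def average_ct(series: PhaseSeries) -> HUVolume:
    """Per-voxel arithmetic mean over all phases (the AVG reconstruction)."""
    if series.n_phases < 2:
        raise GeometryError("need at least two phases to average")
    stack = np.stack([p.values for p in series.phases])
    return series.phases[0].with_values(stack.mean(axis=0))


def mip_ct(series: PhaseSeries) -> HUVolume:
    """Per-voxel maximum over all phases (the MIP reconstruction)."""
    if series.n_phases < 2:
        raise GeometryError("need at least two phases for a maximum projection")
    stack = np.stack([p.values for p in series.phases])
    return series.phases[0].with_values(stack.max(axis=0))


def build_itv(gtv_masks: list[np.ndarray]) -> np.ndarray:
    """Union of the per-phase gross tumor masks: the internal target volume."""
    if not gtv_masks:
        raise GeometryError("no GTV masks given")
    itv = np.zeros_like(gtv_masks[0], dtype=bool)
    for m in gtv_masks:
        if m.shape != itv.shape:
            raise GeometryError("GTV masks do not share a grid")
        itv |= m.astype(bool)
    return itv


def expand_uniform(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Euclidean dilation: include every voxel whose center lies within
    ``margin_mm`` of a set voxel's center."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    mask = mask.astype(bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 1e-9


@dataclass
class StructureSet:
    """GTV (per phase) -> ITV (union) -> PTV (uniform expansion) chain."""

    gtv_masks: list[np.ndarray]
    itv: np.ndarray
    ptv: np.ndarray
    ptv_margin_mm: float

    def __post_init__(self):
        for g in self.gtv_masks:
            if np.any(g & ~self.itv):
                raise GeometryError("GTV not contained in ITV")
        if np.any(self.itv & ~self.ptv):
            raise GeometryError("ITV not contained in PTV")


def build_structures(series: PhaseSeries, ptv_margin_mm: float = 5.0) -> StructureSet:
    itv = build_itv(series.gtv_masks)
    ptv = expand_uniform(itv, ptv_margin_mm, series.phases[0].spacing)
    return StructureSet(
        gtv_masks=[m.astype(bool) for m in series.gtv_masks],
        itv=itv,
        ptv=ptv,
        ptv_margin_mm=ptv_margin_mm,
    )


def override_ptv_density(
    avg: HUVolume, ptv_mask: np.ndarray, itv_mask: np.ndarray
) -> HUVolume:
    """AVG volume with every PTV voxel replaced by the mean gross-tumor HU.

    The replacement value is the mean HU of the AVG volume over the ITV (the
    union gross tumor volume); voxels outside the PTV are untouched.
    """
    if not np.any(ptv_mask):
        raise GeometryError("empty PTV")
    if not np.any(itv_mask):
        raise GeometryError("empty ITV")
    mean_hu = float(avg.values[itv_mask.astype(bool)].mean())
    out = avg.values.copy()
    out[ptv_mask.astype(bool)] = mean_hu
    return avg.with_values(out)


@dataclass
class CalibrationCurve:
    """Piecewise-linear HU -> relative stopping power calibration.

    HU breakpoints must be strictly increasing and stopping power
    nondecreasing; values outside the breakpoint domain are clamped to the
    end breakpoints.
    """

    hu: np.ndarray
    rsp: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.rsp = np.asarray(self.rsp, dtype=float)
        if self.hu.ndim != 1 or self.hu.shape != self.rsp.shape:
            raise CalibrationError("calibration needs matching 1-D HU and RSP arrays")
        if np.any(np.diff(self.hu) <= 0):
            raise CalibrationError("HU breakpoints must be strictly increasing")
        if np.any(self.rsp < 0) or np.any(np.diff(self.rsp) < 0):
            raise CalibrationError("stopping power must be nonnegative and nondecreasing")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self.hu, self.rsp)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.hu, self.rsp]),
            delimiter=",",
            header="hu,rsp",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        arr = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


#: Anchors chosen so that water maps to 1.00 and the liver/lung stopping
#: power ratio at representative HU (~115 vs ~-700) lands in the 3-4x band
#: characteristic of those tissues.
DEFAULT_CALIBRATION = CalibrationCurve(
    hu=np.array([-1000.0, -700.0, -300.0, 0.0, 60.0, 120.0, 1600.0]),
    rsp=np.array([0.001, 0.29, 0.71, 1.00, 1.04, 1.07, 1.85]),
)


def hu_to_rsp(vol: HUVolume, cal: CalibrationCurve | None = None) -> RSPVolume:
    """Convert a HU volume to relative stopping power on the same grid."""
    cal = cal or DEFAULT_CALIBRATION
    return RSPVolume(cal(vol.values), vol.spacing, vol.origin)
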