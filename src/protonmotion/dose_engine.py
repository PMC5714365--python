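"""Broad-beam proton dose computation on a stopping-power volume.

The engine implements the double-scattering field chain: water-equivalent
path length (WEPL) ray tracing along a parallel, axis-aligned beam; an
aperture from the beam's-eye-view (BEV) target projection plus a uniform
margin; a range compensator fitted so every target-crossing ray's distal
surface lands exactly at the prescribed WEPL range R (with a border
smoothing ring, and deliberately no smearing margin); and dose assembly by
evaluating the field's SOBP curve at each voxel's compensated WEPL depth.

Beams are parallel (no source divergence) and restricted to the four
cardinal directions of the axial plane; the aperture "cone" is therefore a
cylinder.  An optional Gaussian penumbra blurs the aperture edge laterally
and is off by default so range behaviour stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beam_model import DEPTH_STEP_CM, DepthDoseCurve, SOBPSpec, build_sobp
from .errors import (
    GeometryError,
    InfeasibleCompensatorError,
    UnsupportedGeometryError,
)
from .volumes import DoseVolume, RSPVolume

# gantry angle (deg, axial plane) -> (beam axis, travel direction along axis)
_ANGLE_MAP = {0: (0, +1), 180: (0, -1), 90: (1, -1), 270: (1, +1)}


@dataclass(frozen=True)
class BeamGeometry:
    """A parallel treatment beam in the axial plane.

    Gantry angles follow the clinical convention restricted to the four
    cardinal directions: 0 anterior, 90 left, 180 posterior, 270 right.
    The two grid axes orthogonal to the beam span the beam's-eye view.
    """

    gantry_angle: float

    def __post_init__(self):
        if int(self.gantry_angle) not in _ANGLE_MAP:
            raise UnsupportedGeometryError(
                f"gantry angle {self.gantry_angle} not in {sorted(_ANGLE_MAP)}; "
                "only cardinal axial directions are supported"
            )

    @property
    def axis(self) -> int:
        return _ANGLE_MAP[int(self.gantry_angle)][0]

    @property
    def direction(self) -> int:
        return _ANGLE_MAP[int(self.gantry_angle)][1]

    @property
    def bev_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.axis)

    def bev_spacing_cm(self, vol) -> tuple[float, float]:
        sp = vol.spacing_cm
        return tuple(sp[a] for a in self.bev_axes)


@dataclass
class BeamField:
    """A fully designed treatment field with frozen hardware."""

    geometry: BeamGeometry
    distal_range_cm: float
    modulation_cm: float
    aperture: np.ndarray  # 2-D bool, BEV
    compensator: np.ndarray  # 2-D float cm WEPL, BEV
    sobp_spec: SOBPSpec
    sobp_curve: DepthDoseCurve
    weight: float = 1.0
    aperture_margin_cm: float = 1.0
    smoothing_margin_cm: float = 1.0
    distal_margin_cm: float = 0.0  # extra range added by a field-specific margin

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ValueError("field weight must be in (0, 1]")
        if not self.aperture.any():
            raise GeometryError("empty aperture")
        if np.any(self.compensator < -1e-9):
            raise GeometryError("negative compensator thickness")

    def summary(self) -> dict:
        return {
            "gantry_angle": self.geometry.gantry_angle,
            "range_cm": round(self.distal_range_cm, 4),
            "sobp_width_cm": round(self.modulation_cm, 4),
            "weight": self.weight,
            "aperture_margin_cm": self.aperture_margin_cm,
            "smoothing_margin_cm": self.smoothing_margin_cm,
            "distal_margin_cm": round(self.distal_margin_cm, 4),
        }


def _oriented(values: np.ndarray, geometry: BeamGeometry) -> np.ndarray:
    if geometry.direction > 0:
        return values
    return np.flip(values, axis=geometry.axis)


def trace_wepl(rsp: RSPVolume, geometry: BeamGeometry) -> np.ndarray:
    """Cumulative WEPL (cm) from the entry surface to each voxel center."""
    v = _oriented(rsp.values, geometry)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise GeometryError("stopping power must be finite and nonnegative")
    step = rsp.spacing_cm[geometry.axis]
    cum = np.cumsum(v, axis=geometry.axis)
    centers = (cum - v / 2.0) * step
    return _oriented(centers, geometry)


def _surface_wepl(ptv_mask, rsp, geometry):
    """Per-BEV-ray WEPL at the entry face of the first and the exit face of
    the last target voxel; NaN on rays that miss the target."""
    v = _oriented(rsp.values, geometry)
    m = _oriented(ptv_mask.astype(bool), geometry)
    step = rsp.spacing_cm[geometry.axis]
    cum = np.cumsum(v, axis=geometry.axis) * step
    exit_w = np.where(m, cum, -np.inf).max(axis=geometry.axis)
    entry_w = np.where(m, cum - v * step, np.inf).min(axis=geometry.axis)
    rays = m.any(axis=geometry.axis)
    distal = np.where(rays, exit_w, np.nan)
    proximal = np.where(rays, entry_w, np.nan)
    return proximal, distal, rays


def design_aperture(
    ptv_mask: np.ndarray, geometry: BeamGeometry, vol, margin_cm: float = 1.0
) -> np.ndarray:
    """BEV projection of the target dilated by a uniform Euclidean margin."""
    if not np.any(ptv_mask):
        raise GeometryError("empty PTV")
    proj = ptv_mask.astype(bool).any(axis=geometry.axis)
    if margin_cm == 0:
        return proj
    dist = ndimage.distance_transform_edt(~proj, sampling=geometry.bev_spacing_cm(vol))
    return dist <= margin_cm + 1e-9


def design_compensator(
    ptv_mask: np.ndarray,
    rsp: RSPVolume,
    geometry: BeamGeometry,
    R: float,
    smoothing_margin_cm: float = 1.0,
) -> np.ndarray:
    """Per-ray degrader conforming the range R to the distal target surface.

    On every ray crossing the target, thickness = R - WEPL(distal target
    surface), so compensated depth to the distal surface is R exactly.
    Rays missing the target take the thickness of the nearest
    target-crossing ray, and a ring of one smoothing margin around the
    projection is mean-filtered (border smoothing); no smearing margin is
    applied.
    """
    if not np.any(ptv_mask):
        raise GeometryError("empty PTV")
    _, distal, rays = _surface_wepl(ptv_mask, rsp, geometry)
    thickness = R - distal
    deficit = float(np.nanmin(thickness))
    if deficit < -1e-9:
        raise InfeasibleCompensatorError(-deficit)

    bev_sp = geometry.bev_spacing_cm(rsp)
    # fill rays outside the projection from the nearest target-crossing ray
    _, (ii, jj) = ndimage.distance_transform_edt(
        ~rays, sampling=bev_sp, return_indices=True
    )
    filled = np.where(rays, thickness, thickness[ii, jj])

    dist_out = ndimage.distance_transform_edt(~rays, sampling=bev_sp)
    ring = (dist_out > 0) & (dist_out <= smoothing_margin_cm + 1e-9)
    if ring.any():
        size = tuple(max(1, int(round(smoothing_margin_cm / s))) for s in bev_sp)
        smoothed = ndimage.uniform_filter(filled, size=size)
        filled = np.where(ring, smoothed, filled)
    return np.clip(filled, 0.0, None)


def fit_field(
    ptv_mask: np.ndarray,
    rsp: RSPVolume,
    geometry: BeamGeometry,
    weight: float = 1.0,
    aperture_margin_cm: float = 1.0,
    smoothing_margin_cm: float = 1.0,
) -> BeamField:
    """Choose R and M so the compensated 90% surfaces bound the target.

    R is the deepest distal-surface WEPL over target rays plus half a depth
    step.  With the compensator in place every ray's distal surface sits at
    R, and the plateau must reach back over the deepest per-ray WEPL chord
    through the target, so M is the maximum chord plus one step.
    """
    if not np.any(ptv_mask):
        raise GeometryError("empty PTV")
    proximal, distal, _rays = _surface_wepl(ptv_mask, rsp, geometry)
    R = float(np.nanmax(distal)) + DEPTH_STEP_CM / 2
    chord = np.nanmax(distal - proximal)
    M = float(min(chord + DEPTH_STEP_CM, R))
    spec, curve = build_sobp(R, M)
    aperture = design_aperture(ptv_mask, geometry, rsp, aperture_margin_cm)
    compensator = design_compensator(ptv_mask, rsp, geometry, R, smoothing_margin_cm)
    return BeamField(
        geometry=geometry,
        distal_range_cm=R,
        modulation_cm=M,
        aperture=aperture,
        compensator=compensator,
        sobp_spec=spec,
        sobp_curve=curve,
        weight=weight,
        aperture_margin_cm=aperture_margin_cm,
        smoothing_margin_cm=smoothing_margin_cm,
    )


def compute_field_dose(
    field: BeamField, rsp: RSPVolume, penumbra_sigma_cm: float | None = None
) -> DoseVolume:
    """Dose (% of prescription) for one field on a stopping-power volume.

    Each voxel's compensated depth is WEPL(voxel) + compensator(ray); the
    field SOBP curve evaluated there, scaled by the field weight, gives the
    voxel dose.  Dose is zero outside the aperture cylinder unless a
    Gaussian penumbra is requested.
    """
    geometry = field.geometry
    wepl = trace_wepl(rsp, geometry)
    comp = np.expand_dims(field.compensator, axis=geometry.axis)
    dose = field.sobp_curve(wepl + comp)
    if penumbra_sigma_cm:
        sig = [penumbra_sigma_cm / s for s in geometry.bev_spacing_cm(rsp)]
        transmission = ndimage.gaussian_filter(field.aperture.astype(float), sig)
    else:
        transmission = field.aperture.astype(float)
    dose = dose * np.expand_dims(transmission, axis=geometry.axis)
    return DoseVolume(100.0 * field.weight * dose, rsp.spacing, rsp.origin)


def compute_plan_dose(
    fields: list[BeamField], rsp: RSPVolume, penumbra_sigma_cm: float | None = None
) -> DoseVolume:
    """Weighted sum of per-field doses (weights must sum to 1)."""
    if not fields:
        raise GeometryError("no fields")
    wsum = sum(f.weight for f in fields)
    if abs(wsum - 1.0) > 1e-6:
        raise ValueError(f"field weights sum to {wsum}, expected 1")
    total = None
    for f in fields:
        d = compute_field_dose(f, rsp, penumbra_sigma_cm)
        total = d if total is None else total.with_values(total.values + d.values)
    return total
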