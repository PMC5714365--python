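"""Synthetic 4D-CT series of a breathing liver-dome tumor.

The phantom emulates the anatomy that makes proton range so motion-sensitive
in liver treatments: a dense liver (100-130 HU) sitting under low-density
lung (-900 to -300 HU), separated by a diaphragm dome that translates
cranio-caudally with breathing, with a soft-tissue body wall around the
axial periphery and a spherical gross tumor riding rigidly on the liver just
beneath the dome apex.  Ten phase volumes (labels 0%, 10%, ..., 90%) sample
one breathing cycle: 0% is end-inspiration (dome most caudal) and 50% is
end-expiration (dome displaced cranially by the full peak-to-peak
amplitude).

The dome is a cone rising from a base plane inside a cylinder of static
soft tissue (the chest wall / mediastinum abstraction): within axial
distance rho <= r0 of the dome axis, the lung/liver interface sits at

    z_if(rho) = z_base + d(phase) + h * (1 - rho / r0),

and everything outside the cylinder is motionless soft tissue.  The
uniform flank slope makes every axial beam ray crossing the dome sweep a
lung/liver wedge whose water-equivalent thickness scales linearly with
the breathing displacement -- a per-ray range swing of a few millimetres
to ~1 cm at 1.3 cm peak-to-peak motion, the regime the compared planning
strategies are designed for.

HU texture (uniform within each tissue interval) and Gaussian noise are
drawn once per seed and shared by all phases, so the phases differ only by
the motion: with amplitude zero all phases are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, InvalidPhaseError
from .volumes import HUVolume, load_mask, load_nifti, save_nifti

PHASE_LABELS = tuple(range(0, 100, 10))


@dataclass
class PhantomConfig:
    """Geometry, tissue and motion parameters of the synthetic patient.

    Lengths are mm unless suffixed otherwise; the peak-to-peak breathing
    amplitude is cm to match how liver-dome motion is usually reported.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing: float = 2.0  # mm, isotropic
    peak_to_peak_amplitude_cm: float = 1.3
    tumor_center: tuple[float, float, float] = (95.0, 95.0, 105.0)
    tumor_diameter: float = 30.0
    hu_liver: tuple[float, float] = (100.0, 130.0)
    hu_lung: tuple[float, float] = (-900.0, -300.0)
    hu_tumor: float = 60.0
    hu_soft_tissue: float = 40.0
    n_phases: int = 10
    noise_sd: float = 10.0
    seed: int = 0
    # Diaphragm dome: cone of base radius dome_radius and height dome_height
    # on a base plane at dome_base_z, inside a cylinder of static soft
    # tissue; soft-tissue body wall of wall_thickness around the periphery.
    dome_base_z: float = 58.0
    dome_height: float = 114.0
    dome_radius: float = 81.4
    wall_thickness: float = 20.0
    # Narrow lung invagination above the tumor (a recess-like notch that
    # rides on the liver): its tip sits notch_clearance above the tumor top
    # and it widens upward with notch_slope (mm of height per mm of radius).
    # It puts a small part of the PTV into lung at inspiratory phases, the
    # feature the density-override strategy corrects.  Set notch_slope to
    # None (or 0) to disable.
    notch_clearance: float = 3.0
    notch_slope: float | None = 4.5

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.peak_to_peak_amplitude_cm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tumor_diameter <= 0:
            raise ValueError("tumor diameter must be positive")
        for name in ("hu_liver", "hu_lung"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} interval is inverted")

    @property
    def phase_labels(self) -> tuple[int, ...]:
        return tuple(int(round(100 * k / self.n_phases)) for k in range(self.n_phases))


@dataclass
class PhaseSeries:
    """An ordered 4D-CT phase series with per-phase gross tumor masks."""

    phases: list[HUVolume]
    gtv_masks: list[np.ndarray]
    labels: tuple[int, ...]
    amplitude_cm: float
    phase_weights: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.phases) != len(self.gtv_masks):
            raise GeometryError("one GTV mask is required per phase")
        ref = self.phases[0]
        for p in self.phases[1:]:
            ref.require_same_grid(p)
        for m in self.gtv_masks:
            if m.shape != ref.shape:
                raise GeometryError("GTV mask grid does not match the phase volumes")
            if not m.any():
                raise GeometryError("empty GTV mask")
        if self.phase_weights is None:
            self.phase_weights = np.full(len(self.phases), 1.0 / len(self.phases))
        self.phase_weights = np.asarray(self.phase_weights, dtype=float)
        if abs(self.phase_weights.sum() - 1.0) > 1e-9:
            raise ValueError("phase weights must sum to 1")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def phase(self, label: int) -> HUVolume:
        return self.phases[self.labels.index(label)]

    def gtv(self, label: int) -> np.ndarray:
        return self.gtv_masks[self.labels.index(label)]


def motion_displacement(phase_label: int, amplitude_cm: float) -> float:
    """Cranial displacement (cm) of the liver at one respiratory phase.

    A sinusoidal surrogate anchored to the 4D-CT phase convention:
    0 at the 0% (end-inspiration) phase and the full peak-to-peak
    amplitude at the 50% (end-expiration) phase,

        d(p) = A * (1 - cos(2*pi*p/100)) / 2.
    """
    if phase_label not in PHASE_LABELS:
        raise InvalidPhaseError(
            f"phase label {phase_label!r} not in {sorted(PHASE_LABELS)}"
        )
    if amplitude_cm < 0:
        raise ValueError("amplitude must be >= 0")
    return _displacement(phase_label, amplitude_cm)


def _displacement(phase_percent: float, amplitude_cm: float) -> float:
    # Same sinusoid without the 10-phase label check (used for n_phases != 10).
    return amplitude_cm * (1.0 - np.cos(2.0 * np.pi * phase_percent / 100.0)) / 2.0


def _smooth_texture(rng, shape, spacing_mm, interval, corr_mm=6.0):
    """Spatially correlated tissue texture spanning a HU interval.

    White noise smoothed to a ~``corr_mm`` correlation length, centred on
    the interval midpoint with a standard deviation of one twelfth of the
    interval width, and clipped to the interval: parenchyma is locally
    near-homogeneous at the millimetre scale while every voxel stays
    within the tissue's reported HU range.
    """
    from scipy import ndimage

    lo, hi = interval
    if hi == lo:
        return np.full(shape, float(lo))
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_mm / spacing_mm)
    smooth /= smooth.std() or 1.0
    center, width = (hi + lo) / 2.0, hi - lo
    return np.clip(center + width / 12.0 * smooth, lo, hi)


def _interface_height(config: PhantomConfig, rho: np.ndarray, disp_mm: float):
    flank = config.dome_height * np.clip(1.0 - rho / config.dome_radius, 0.0, None)
    return config.dome_base_z + disp_mm + flank


def generate_phase_series(config: PhantomConfig) -> PhaseSeries:
    """Build the deterministic synthetic 4D-CT series for one configuration."""
    sp = config.voxel_spacing
    nx, ny, nz = config.grid_shape
    x = sp * np.arange(nx)[:, None, None]
    y = sp * np.arange(ny)[None, :, None]
    z = sp * np.arange(nz)[None, None, :]
    cx, cy, cz = config.tumor_center
    rho = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)  # axial distance from dome axis

    extent = (sp * (nx - 1), sp * (ny - 1), sp * (nz - 1))
    r_t = config.tumor_diameter / 2.0
    max_disp = max(
        10.0 * _displacement(lbl, config.peak_to_peak_amplitude_cm)
        for lbl in config.phase_labels
    )
    lo = (cx - r_t, cy - r_t, cz - r_t)
    hi = (cx + r_t, cy + r_t, cz + r_t + max_disp)
    if any(a < 0 for a in lo) or any(b > e for b, e in zip(hi, extent)):
        raise GeometryError("tumor sphere leaves the grid during the breathing cycle")

    rng = np.random.default_rng(config.seed)
    liver_tex = _smooth_texture(rng, config.grid_shape, sp, config.hu_liver)
    lung_tex = _smooth_texture(rng, config.grid_shape, sp, config.hu_lung)
    noise = (
        rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        if config.noise_sd > 0
        else 0.0
    )

    wt = config.wall_thickness
    wall = (
        (x < wt) | (x > extent[0] - wt) | (y < wt) | (y > extent[1] - wt)
    ) & np.ones(config.grid_shape, dtype=bool)

    inside_dome = np.broadcast_to(rho <= config.dome_radius, config.grid_shape)
    tumor_top = cz + config.tumor_diameter / 2.0
    phases, masks = [], []
    for lbl in config.phase_labels:
        d_mm = 10.0 * _displacement(lbl, config.peak_to_peak_amplitude_cm)
        interface = _interface_height(config, rho, d_mm)
        liver = np.broadcast_to(z, config.grid_shape) < interface
        if config.notch_slope:
            tip = tumor_top + config.notch_clearance + d_mm
            notch = np.broadcast_to(
                z - tip > config.notch_slope * rho, config.grid_shape
            )
            liver = liver & ~notch
        hu = np.where(liver, liver_tex, lung_tex)
        # outside the dome cylinder the anatomy is motionless chest
        # wall / mediastinum soft tissue
        hu = np.where(inside_dome, hu, config.hu_soft_tissue)
        gtv = (x - cx) ** 2 + (y - cy) ** 2 + (z - (cz + d_mm)) ** 2 <= r_t**2
        hu = np.where(gtv, config.hu_tumor, hu)
        hu = np.where(wall, config.hu_soft_tissue, hu)
        hu = hu + noise
        phases.append(HUVolume(hu, (sp, sp, sp)))
        masks.append(gtv)

    return PhaseSeries(
        phases=phases,
        gtv_masks=masks,
        labels=config.phase_labels,
        amplitude_cm=config.peak_to_peak_amplitude_cm,
    )


def save_series(series: PhaseSeries, out_dir) -> None:
    """Write one NIfTI per phase HU volume and GTV mask plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lbl, vol, mask in zip(series.labels, series.phases, series.gtv_masks):
        save_nifti(vol, out / f"phase_{lbl:02d}.nii.gz", dtype=np.float32)
        save_nifti(vol.with_values(mask), out / f"gtv_{lbl:02d}.nii.gz")
    sidecar = {
        "labels": list(series.labels),
        "amplitude_cm": series.amplitude_cm,
        "phase_weights": series.phase_weights.tolist(),
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=2))


def load_series(in_dir) -> PhaseSeries:
    src = Path(in_dir)
    meta = json.loads((src / "series.json").read_text())
    phases, masks = [], []
    for lbl in meta["labels"]:
        phases.append(load_nifti(src / f"phase_{lbl:02d}.nii.gz", HUVolume))
        masks.append(load_mask(src / f"gtv_{lbl:02d}.nii.gz")[0])
    return PhaseSeries(
        phases=phases,
        gtv_masks=masks,
        labels=tuple(meta["labels"]),
        amplitude_cm=meta["amplitude_cm"],
        phase_weights=np.asarray(meta["phase_weights"]),
    )


def config_to_json(config: PhantomConfig) -> str:
    return json.dumps(asdict(config), indent=2)
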