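"""One-dimensional proton depth-dose physics.

Pristine Bragg curves use a Bortfeld-style analytic model: a power-law
stopping term plus a fluence-loss term,

    f(z) ~ 17.93 (R - z)^(-0.435) + (0.444 + 3.17 / R) (R - z)^0.565,

numerically convolved with a Gaussian range-straggling kernel of width
sigma = 0.012 R^0.935 (cm).  A spread-out Bragg peak (SOBP) is a
nonnegative-least-squares superposition of pristine peaks tuned so the
summed curve is flat on the modulation plateau, with the distal range R and
modulation width M defined on the 90% dose levels: R is the depth of the
distal 90% crossing and M the distance between the proximal and distal 90%
crossings.  Because every downstream plan metric is defined relative to
those 90% levels, the peak positions are iteratively calibrated until the
composed curve hits the requested R and M on its own 90% crossings.

Depths are water-equivalent path length (WEPL) in cm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.optimize import nnls

from .errors import SOBPFlatnessError

#: depth grid step (cm WEPL) -- finer than any margin decided downstream
DEPTH_STEP_CM = 0.05


@dataclass
class DepthDoseCurve:
    """Relative dose vs depth (cm WEPL) on a uniform grid."""

    depths: np.ndarray
    dose: np.ndarray
    nominal_range: float

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        steps = np.diff(self.depths)
        if np.any(steps <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.dose < -1e-12):
            raise ValueError("dose must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.depths[1] - self.depths[0])

    def __call__(self, depth):
        """Evaluate by linear interpolation; zero beyond the distal tail."""
        return np.interp(depth, self.depths, self.dose, left=self.dose[0], right=0.0)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.depths, self.dose]),
            delimiter=",",
            header="depth_cm,dose",
            comments="",
        )


@dataclass
class SOBPSpec:
    """Pristine-peak decomposition of a spread-out Bragg peak."""

    distal_range_cm: float
    modulation_cm: float
    peak_spacing_cm: float
    peak_ranges_cm: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if not 0 < self.modulation_cm <= self.distal_range_cm:
            raise ValueError("need 0 < M <= R")
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("pristine-peak weights must be nonnegative")


def straggling_sigma(range_cm: float) -> float:
    """Gaussian range-straggling width (cm) for a beam of the given range."""
    return 0.012 * range_cm**0.935


def pristine_bragg(range_cm: float, depths: np.ndarray | None = None) -> DepthDoseCurve:
    """Analytic pristine Bragg curve with peak dose normalized to 1."""
    if range_cm <= 0:
        raise ValueError("range must be positive")
    if depths is None:
        depths = np.arange(0.0, range_cm + 3.0 + DEPTH_STEP_CM / 2, DEPTH_STEP_CM)
    dose = _pristine_matrix(np.array([range_cm]), np.asarray(depths, float))[0]
    return DepthDoseCurve(depths, dose, nominal_range=range_cm)


def _pristine_matrix(ranges: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Rows of peak-normalized pristine curves sampled on ``depths``."""
    fine = 0.01  # cm; evaluation grid for the straggling convolution
    out = np.empty((ranges.size, depths.size))
    for i, R in enumerate(ranges):
        sigma = straggling_sigma(R)
        half = max(5.0 * sigma, 5 * fine)
        zf = np.arange(
            max(0.0, depths[0] - half), depths[-1] + half + fine / 2, fine
        )
        u = np.clip(R - zf, fine / 2, None)
        f = 17.93 * u**-0.435 + (0.444 + 3.17 / R) * u**0.565
        f[zf > R] = 0.0
        k = np.arange(-ceil(half / fine), ceil(half / fine) + 1) * fine
        kern = np.exp(-0.5 * (k / sigma) ** 2)
        kern /= kern.sum()
        conv = np.convolve(f, kern, mode="same")
        row = np.interp(depths, zf, conv)
        out[i] = row / conv.max()
    return out


def _threshold_indices(dose: np.ndarray, level: float):
    if dose.max() <= 0:
        raise ValueError("curve carries no dose")
    above = dose >= level
    if not above.any():
        raise ValueError("dose never reaches the 90% level")
    first = int(np.argmax(above))
    last = int(len(dose) - 1 - np.argmax(above[::-1]))
    return first, last


def find_distal_90(curve: DepthDoseCurve) -> float:
    """Deepest depth where dose crosses 90% of the curve maximum."""
    thr = 0.9 * curve.dose.max()
    _, last = _threshold_indices(curve.dose, thr)
    if last == len(curve.dose) - 1:
        return float(curve.depths[last])
    d0, d1 = curve.dose[last], curve.dose[last + 1]
    frac = (d0 - thr) / (d0 - d1)
    return float(curve.depths[last] + frac * curve.step)


def find_proximal_90(curve: DepthDoseCurve) -> float:
    """Shallowest depth where dose crosses 90% of the curve maximum."""
    thr = 0.9 * curve.dose.max()
    first, _ = _threshold_indices(curve.dose, thr)
    if first == 0:
        return float(curve.depths[0])
    d0, d1 = curve.dose[first - 1], curve.dose[first]
    frac = (thr - d0) / (d1 - d0)
    return float(curve.depths[first - 1] + frac * curve.step)


def sobp_width(curve: DepthDoseCurve) -> float:
    return find_distal_90(curve) - find_proximal_90(curve)


def _fit_weights(R, M, off_d, off_p, n_peaks, spacing, step):
    """One NNLS fit of pristine weights for shifted peak-range endpoints."""
    r_max = R + off_d
    r_min = float(np.clip(R - M + off_p, 0.3, r_max - 2 * step))
    ranges = np.linspace(r_min, r_max, n_peaks)
    depths = np.arange(0.0, r_max + 2.0 + step / 2, step)
    basis = _pristine_matrix(ranges, depths)
    # extend the fit region slightly proximal of the shallowest peak so its
    # own maximum is constrained (otherwise NNLS grows an unpenalized horn
    # just outside the target window)
    guard = max(2 * step, 3 * straggling_sigma(max(r_min, 0.3)))
    sel = (depths >= r_min - guard) & (depths <= r_max)
    weights, _ = nnls(basis[:, sel].T, np.ones(int(sel.sum())))
    total = weights @ basis
    curve = DepthDoseCurve(depths, total, nominal_range=R)
    e_d = R - find_distal_90(curve)
    e_p = (R - M) - find_proximal_90(curve)
    clamped = r_min <= 0.3 + 1e-9 and e_p < 0
    return {
        "ranges": ranges,
        "depths": depths,
        "total": total,
        "weights": weights,
        "e_d": e_d,
        "e_p": e_p,
        "clamped": clamped,
        "score": max(abs(e_d), 0.0 if clamped else abs(e_p)),
    }


def build_sobp(
    R: float,
    M: float,
    step: float = DEPTH_STEP_CM,
    flatness_tol: float = 0.02,
    max_iter: int = 40,
) -> tuple[SOBPSpec, DepthDoseCurve]:
    """Synthesize an SOBP whose distal/proximal 90% crossings land on R and R-M.

    Nonnegative least squares fits pristine-peak weights to a flat plateau;
    a damped outer loop shifts the deepest/shallowest pristine ranges until
    the composed curve's own 90% crossings match the request, with a final
    scalar polish of the proximal shift if needed.

    The flat plateau is guaranteed on ``[R - M + dp, R - 3*spacing]`` with
    ``dp = max(0.55, 0.1*M)`` cm: because pristine peaks have slow
    power-law proximal shoulders, the region between the proximal 90%
    crossing and full plateau dose (the proximal knee) is a few millimetres
    to ~1 cm wide and cannot be flat by construction.  Raises
    :class:`SOBPFlatnessError` if the plateau ripple exceeds
    ``flatness_tol``.
    """
    if not 0 < M <= R:
        raise ValueError("need 0 < M <= R")
    sigma = straggling_sigma(R)
    falloff_80_20 = 1.683 * sigma  # Gaussian 80%-20% distal falloff
    spacing = max(0.6 * falloff_80_20, 2 * step)
    n_peaks = max(2, int(ceil(M / spacing)) + 1)

    off_d = off_p = 0.0
    best = None
    best_off = (0.0, 0.0)
    for it in range(max_iter):
        fit = _fit_weights(R, M, off_d, off_p, n_peaks, spacing, step)
        if best is None or fit["score"] < best["score"]:
            best, best_off = fit, (off_d, off_p)
        if abs(fit["e_d"]) < step / 4 and (
            abs(fit["e_p"]) < step / 4 or fit["clamped"]
        ):
            break
        gain = 0.7 * 0.5 ** (it // 8)  # damp harder if oscillating
        off_d += gain * float(np.clip(fit["e_d"], -0.4, 0.4))
        off_p += gain * float(np.clip(fit["e_p"], -0.4, 0.4))
    if best["score"] >= step / 2 and not best["clamped"]:
        # scalar polish: scan the proximal shift around the best iterate
        off_d, off_p = best_off
        for doff in (-0.075, -0.05, -0.025, 0.025, 0.05, 0.075):
            fit = _fit_weights(R, M, off_d, off_p + doff, n_peaks, spacing, step)
            if fit["score"] < best["score"]:
                best, best_off = fit, (off_d, off_p + doff)

    depths, total, weights = best["depths"], best["total"], best["weights"]
    ranges = best["ranges"]

    # normalize the guaranteed-flat plateau to dose 1.0 and check its ripple
    lo = R - M + max(0.55, 0.1 * M)
    hi = R - 3 * spacing
    sel = (depths >= lo) & (depths <= hi)
    if sel.sum() >= 2:
        plateau_dose = float(total[sel].mean())
        total = total / plateau_dose
        weights = weights / plateau_dose
        ripple = float(np.abs(total[sel] - 1.0).max())
        if ripple > flatness_tol:
            raise SOBPFlatnessError(ripple, flatness_tol)
    else:  # degenerate, near-pristine modulation
        peak = float(total.max())
        total, weights = total / peak, weights / peak
    curve = DepthDoseCurve(depths, total, nominal_range=R)
    spec = SOBPSpec(
        distal_range_cm=R,
        modulation_cm=M,
        peak_spacing_cm=spacing,
        peak_ranges_cm=ranges,
        weights=weights,
    )
    return spec, curve
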