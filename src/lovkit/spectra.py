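"""Absorption/emission spectrum processing.

Covers the spectral arithmetic used when characterising a flavin-binding
photoreceptor: Savitzky–Golay second-derivative spectroscopy of the
aromatic UV window (tyrosine ~277 nm, tryptophan ~283 nm minima), the
vibronic shoulder-to-maximum ratio A_sh/A_max of the flavin S0->S1 band,
isosbestic points between dark- and light-adapted spectra, and emission
band metrics (peak position, FWHM).

The second derivative is computed with a 9-point, 3rd-order Savitzky–Golay
differentiator and then refined by cubic-spline interpolation to a
0.01–0.02 nm grid; differentiation precedes spline refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .exceptions import DegenerateDataError, InputError


@dataclass
class Spectrum:
    """Wavelength-indexed signal (absorbance AU or fluorescence counts)."""

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise InputError("wavelengths and values differ in length")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise InputError("spectrum needs >= 2 samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if not (
            np.all(np.isfinite(self.wavelengths))
            and np.all(np.isfinite(self.values))
        ):
            raise InputError("spectrum contains non-finite values")

    def interpolate(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.interp(wavelengths, self.wavelengths, self.values)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * factor, dict(self.meta))


@dataclass
class DerivativeSpectrum:
    """Second derivative on a refined wavelength grid with provenance."""

    wavelengths: np.ndarray
    values: np.ndarray
    window: int
    order: int
    refine_step: float
    resampled: bool = False


@dataclass
class BandMetrics:
    """Band descriptors: peak position/height, shoulder ratio, FWHM."""

    lambda_max: float
    a_max: float
    a_sh: float | None = None
    ratio: float | None = None
    fwhm: float | None = None


def _uniform_grid(spec: Spectrum) -> tuple[np.ndarray, np.ndarray, bool]:
    steps = np.diff(spec.wavelengths)
    if np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        return spec.wavelengths, spec.values, False
    # resample non-uniform sampling to a uniform grid at the median step
    step = float(np.median(steps))
    grid = np.arange(
        spec.wavelengths[0], spec.wavelengths[-1] + step / 2, step
    )
    return grid, spec.interpolate(grid), True


def second_derivative(
    spec: Spectrum,
    window: int = 9,
    order: int = 3,
    refine_step: float = 0.02,
) -> DerivativeSpectrum:
    """Savitzky–Golay second derivative, spline-refined to a fine grid.

    Endpoints within half a window of the edges are excluded before the
    cubic-spline refinement; ``refine_step`` must lie in [0.01, 0.02] nm.
    """
    if window % 2 == 0:
        raise InputError("window must be odd")
    if order >= window:
        raise InputError("polynomial order must be < window")
    if order < 2:
        raise InputError("second derivative needs polynomial order >= 2")
    if not 0.01 <= refine_step <= 0.02:
        raise InputError("refine_step must be within [0.01, 0.02] nm")
    grid, values, resampled = _uniform_grid(spec)
    if grid.size < window:
        raise InputError(
            f"spectrum has {grid.size} points; window {window} too large"
        )
    step = float(grid[1] - grid[0])
    deriv = savgol_filter(values, window, order, deriv=2, delta=step)
    # flatten pure round-off so flat/linear spectra do not grow spurious
    # extrema on the refined grid
    floor = 1e-13 * np.abs(values).max() / step**2
    deriv[np.abs(deriv) < floor] = 0.0
    half = window // 2
    core_w = grid[half : grid.size - half]
    core_d = deriv[half : grid.size - half]
    if core_w.size < 4:
        raise InputError("too few interior points after edge exclusion")
    spline = CubicSpline(core_w, core_d)
    fine = np.arange(core_w[0], core_w[-1] + refine_step / 2, refine_step)
    fine = fine[fine <= core_w[-1] + 1e-12]
    return DerivativeSpectrum(
        wavelengths=fine,
        values=spline(fine),
        window=window,
        order=order,
        refine_step=refine_step,
        resampled=resampled,
    )


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def find_uv_minima(
    d: DerivativeSpectrum,
    lo: float = 265.0,
    hi: float = 285.0,
    min_depth_frac: float = 1e-6,
) -> list[tuple[float, float]]:
    """Local minima of the second derivative in [lo, hi], ascending λ.

    Positions are refined parabolically on the interpolated grid; the
    returned depth is the derivative value at the minimum.  Candidates
    whose depth is below ``min_depth_frac`` of the deepest minimum in the
    window are interpolation ripple, not bands, and are dropped.
    """
    mask = (d.wavelengths >= lo) & (d.wavelengths <= hi)
    if not mask.any():
        raise InputError(f"window [{lo}, {hi}] nm is outside the grid")
    idx = np.flatnonzero(mask)
    out = []
    for i in idx:
        if i == 0 or i == d.values.size - 1:
            continue
        if d.values[i] < d.values[i - 1] and d.values[i] <= d.values[i + 1]:
            lam, depth = _parabolic_refine(d.wavelengths, d.values, i)
            out.append((lam, depth))
    if out:
        scale = max(abs(depth) for _, depth in out)
        out = [
            (lam, depth)
            for lam, depth in out
            if abs(depth) >= min_depth_frac * scale
        ]
    return out


def shoulder_ratio(
    spec: Spectrum,
    max_window: tuple[float, float] = (440.0, 450.0),
    shoulder_nm: float = 472.0,
) -> BandMetrics:
    """A_sh/A_max of a flavin band: shoulder vs main-band absorbance.

    A_max is the maximum inside ``max_window`` (λ_max its argmax); A_sh is
    the linearly interpolated absorbance at the shoulder wavelength
    (default 472 nm, the flavin vibronic shoulder).
    """
    lo, hi = max_window
    if spec.wavelengths[0] > lo or spec.wavelengths[-1] < max(hi, shoulder_nm):
        raise InputError("spectrum does not cover the requested windows")
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not mask.any():
        raise InputError("empty maximum window")
    sub_w = spec.wavelengths[mask]
    sub_v = spec.values[mask]
    i = int(np.argmax(sub_v))
    a_max = float(sub_v[i])
    if a_max <= 0:
        raise DegenerateDataError("non-positive band maximum")
    a_sh = float(spec.interpolate(np.array([shoulder_nm]))[0])
    return BandMetrics(
        lambda_max=float(sub_w[i]),
        a_max=a_max,
        a_sh=a_sh,
        ratio=a_sh / a_max,
    )


@dataclass
class IsosbesticResult:
    """Zero crossings of the difference of two spectra."""

    points: list[float]
    degenerate: bool = False

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


def isosbestic_points(
    a: Spectrum,
    b: Spectrum,
    lo: float | None = None,
    hi: float | None = None,
) -> IsosbesticResult:
    """Wavelengths where two spectra cross (a − b changes sign).

    Both spectra are resampled to a common grid on their overlap; crossings
    are located by linear interpolation between bracketing samples.  When
    the two spectra are identical (a − b ≡ 0 within numerical tolerance)
    the result is empty and flagged degenerate.
    """
    start = max(a.wavelengths[0], b.wavelengths[0])
    stop = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo is not None:
        start = max(start, lo)
    if hi is not None:
        stop = min(stop, hi)
    if start >= stop:
        raise InputError("spectra do not overlap in the requested window")
    step = min(
        float(np.min(np.diff(a.wavelengths))),
        float(np.min(np.diff(b.wavelengths))),
    )
    grid = np.linspace(start, stop, max(int(round((stop - start) / step)) + 1, 2))
    diff = a.interpolate(grid) - b.interpolate(grid)
    scale = max(np.abs(a.interpolate(grid)).max(), np.abs(b.interpolate(grid)).max())
    if scale == 0 or np.abs(diff).max() < 1e-12 * max(scale, 1.0):
        return IsosbesticResult(points=[], degenerate=True)
    points = []
    sign = np.sign(diff)
    for i in range(diff.size - 1):
        if sign[i] == 0:
            points.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            w = diff[i] / (diff[i] - diff[i + 1])
            points.append(float(grid[i] + w * (grid[i + 1] - grid[i])))
    if sign[-1] == 0:
        points.append(float(grid[-1]))
    return IsosbesticResult(points=points)


def emission_metrics(spec: Spectrum) -> BandMetrics:
    """Peak position (parabolic refinement) and FWHM of an emission band.

    The FWHM is measured by linear interpolation at half maximum on both
    flanks; if either flank never falls below half maximum the band is not
    bracketed and an error is raised.
    """
    i = int(np.argmax(spec.values))
    lam_max, a_max = _parabolic_refine(spec.wavelengths, spec.values, i)
    if a_max <= 0:
        raise DegenerateDataError("non-positive emission maximum")
    half = a_max / 2.0
    w, v = spec.wavelengths, spec.values

    def cross(side: str) -> float:
        rng = range(i, 0, -1) if side == "left" else range(i, v.size - 1)
        for j in rng:
            k = j - 1 if side == "left" else j + 1
            if v[k] <= half < v[j] or (v[k] <= half and v[j] >= half):
                frac = (v[j] - half) / (v[j] - v[k])
                return float(w[j] + frac * (w[k] - w[j]))
        raise DegenerateDataError(
            f"half-maximum not bracketed on the {side} flank"
        )

    left = cross("left")
    right = cross("right")
    return BandMetrics(
        lambda_max=lam_max, a_max=a_max, fwhm=right - left
    )
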