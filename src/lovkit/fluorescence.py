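"""Steady-state and time-resolved fluorescence of a flavin chromophore.

Steady state: relative quantum yield against free FMN (Φ_ref = 0.26),
L-format anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with the
instrumental G factor I_HV/I_HH.

Time resolved (TCSPC): multiexponential intensity decay

    I(t) = Σ_i α_i exp(−t/τ_i)

fitted by iterative reconvolution with the measured instrument response
function (IRF) on the histogram grid, Poisson-weighted.  Amplitudes enter
linearly, so the fit separates: the nonlinear search runs over {log τ_i,
IRF shift} while the α_i are solved by nonnegative least squares at each
step (variable projection).  Derived quantities follow the standard
definitions: fractional contributions f_i = α_i τ_i / Σ α_j τ_j and the
intensity-weighted average lifetime τ_av = Σ f_i τ_i.

Anisotropy decay is fitted with the spherical-rotor model
r(t) = r0 exp(−t/θ); the Perrin relation θ = τ_av/(r0/r − 1) links the
steady-state anisotropy to the rotational correlation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares, nnls

from .exceptions import DegenerateDataError, FitError, InputError

#: theoretical one-photon limit for the fundamental anisotropy
R0_MAX_DEFAULT = 0.4


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


@dataclass
class PolarizedIntensities:
    """The four polarizer-geometry intensities (scalars or spectra)."""

    i_vv: np.ndarray | float
    i_vh: np.ndarray | float
    i_hv: np.ndarray | float
    i_hh: np.ndarray | float
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrs = [np.asarray(x, dtype=float) for x in
                (self.i_vv, self.i_vh, self.i_hv, self.i_hh)]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise InputError("polarized intensities must share one shape")
        for a in arrs:
            if np.any(a < 0):
                raise InputError("intensities must be nonnegative")
        self.i_vv, self.i_vh, self.i_hv, self.i_hh = arrs


def g_factor(i_hv, i_hh) -> float:
    """Instrumental sensitivity ratio G = I_HV / I_HH.

    Spectral inputs are reduced to the mean of the pointwise ratio.
    """
    hv = np.asarray(i_hv, dtype=float)
    hh = np.asarray(i_hh, dtype=float)
    if np.any(hh <= 0):
        raise InputError("I_HH must be positive")
    return float(np.mean(hv / hh))


def steady_anisotropy(p: PolarizedIntensities, g: float):
    """L-format steady-state anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH).

    Returns a scalar for scalar intensities, an array for spectra.
    """
    if g <= 0:
        raise InputError("G factor must be positive")
    denom = p.i_vv + 2.0 * g * p.i_vh
    if np.any(np.asarray(denom) <= 0):
        raise InputError("anisotropy denominator must be positive")
    r = (p.i_vv - g * p.i_vh) / denom
    return float(r) if np.ndim(r) == 0 else r


def band_averaged_anisotropy(
    wavelengths: np.ndarray,
    r_lambda: np.ndarray,
    center: float,
    half_width: float = 5.0,
) -> float:
    """Mean anisotropy over center ± half_width nm (default ±5 nm band)."""
    w = np.asarray(wavelengths, dtype=float)
    r = np.asarray(r_lambda, dtype=float)
    mask = (w >= center - half_width) & (w <= center + half_width)
    if not mask.any():
        raise InputError("averaging band is outside the spectrum")
    return float(r[mask].mean())


def relative_quantum_yield(
    f_sample: float,
    f_ref: float,
    a_sample: float,
    a_ref: float,
    phi_ref: float = 0.26,
) -> float:
    """Fluorescence quantum yield relative to a reference fluorophore.

    Φ = Φ_ref · (F_sample/F_ref) · (A_ref/A_sample) with F the integrated
    emission and A the absorbance at the excitation wavelength.  The
    default reference is free FMN in water (Φ_ref = 0.26).  Absorbances
    above 0.2 trigger an inner-filter warning.
    """
    for name, val in (("F_sample", f_sample), ("F_ref", f_ref),
                      ("A_sample", a_sample), ("A_ref", a_ref),
                      ("phi_ref", phi_ref)):
        if val <= 0:
            raise InputError(f"{name} must be positive")
    if a_sample > 0.2 or a_ref > 0.2:
        warnings.warn(
            "absorbance above 0.2: inner-filter effects may bias the yield",
            stacklevel=2,
        )
    return phi_ref * (f_sample / f_ref) * (a_ref / a_sample)


# ---------------------------------------------------------------------------
# Lifetime arithmetic
# ---------------------------------------------------------------------------


def fractional_contributions(
    alpha: Sequence[float], tau: Sequence[float]
) -> np.ndarray:
    """f_i = α_i τ_i / Σ α_j τ_j (share of steady-state intensity)."""
    a = np.asarray(alpha, dtype=float)
    t = np.asarray(tau, dtype=float)
    if a.shape != t.shape:
        raise InputError("alpha and tau differ in length")
    if np.any(a <= 0) or np.any(t <= 0):
        raise InputError("alpha and tau must be positive")
    w = a * t
    return w / w.sum()


def average_lifetime(tau: Sequence[float], f: Sequence[float]) -> float:
    """Intensity-weighted average lifetime τ_av = Σ f_i τ_i.

    ``f`` must sum to 1 within ±0.01 (renormalised with a warning inside
    that band, rejected outside it).
    """
    t = np.asarray(tau, dtype=float)
    fr = np.asarray(f, dtype=float)
    if t.shape != fr.shape:
        raise InputError("tau and f differ in length")
    s = fr.sum()
    if abs(s - 1.0) > 0.01:
        raise InputError(f"fractional contributions sum to {s:.4f}, not 1")
    if not np.isclose(s, 1.0, atol=1e-12):
        warnings.warn(
            f"fractional contributions sum to {s:.4f}; renormalising",
            stacklevel=2,
        )
        fr = fr / s
    return float((fr * t).sum())


# ---------------------------------------------------------------------------
# TCSPC decay fitting
# ---------------------------------------------------------------------------


@dataclass
class DecayHistogram:
    """TCSPC photon-count histogram with its instrument response."""

    times: np.ndarray  # ns, uniform bins
    counts: np.ndarray
    irf_counts: np.ndarray
    lambda_ex: float = 461.0
    lambda_em: float = 500.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        if not (self.times.shape == self.counts.shape == self.irf_counts.shape):
            raise InputError("times, counts and IRF must share one length")
        steps = np.diff(self.times)
        if self.times.size < 8 or np.any(steps <= 0):
            raise InputError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise InputError("histogram bins must be uniform")
        if self.counts.sum() <= 0:
            raise InputError("histogram has no counts")
        if np.any(self.counts < 0) or np.any(self.irf_counts < 0):
            raise InputError("counts must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class MultiExpFitResult:
    """Multiexponential decay fit: amplitudes, lifetimes, χ², τ_av."""

    n_components: int
    alpha: np.ndarray  # amplitudes at t = 0 (counts/bin scale), τ-ascending
    tau: np.ndarray  # ns
    f: np.ndarray  # fractional contributions, sum 1
    tau_av: float  # ns
    chi2_reduced: float
    chi2_defined: bool
    shift: float  # ns, fitted IRF-decay offset
    reconvolved: bool
    model_counts: np.ndarray = field(repr=False)
    histogram: DecayHistogram = field(repr=False)

    def summary(self) -> str:
        lines = [
            f"TCSPC decay fit ({self.n_components} components, "
            f"{'reconvolution' if self.reconvolved else 'tail fit'})",
            "-" * 56,
            f"emission wavelength : {self.histogram.lambda_em:.0f} nm",
            f"total counts        : {self.histogram.counts.sum():.3g}",
        ]
        for i, (a, t, fi) in enumerate(zip(self.alpha, self.tau, self.f), 1):
            lines.append(
                f"  tau_{i} = {t:8.4f} ns   f_{i} = {100 * fi:6.2f} %   "
                f"alpha_{i} = {a:.4g}"
            )
        chi = f"{self.chi2_reduced:.3f}" if self.chi2_defined else "undefined"
        lines += [
            f"tau_av              : {self.tau_av:.4f} ns",
            f"IRF shift           : {self.shift:.4f} ns",
            f"reduced chi^2       : {chi}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.histogram
        ax.semilogy(h.times, np.maximum(h.counts, 0.1), ".", ms=2,
                    label="data")
        ax.semilogy(h.times, np.maximum(self.model_counts, 0.1), "-",
                    label="fit")
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("counts")
        ax.legend()
        return ax


def _shifted_irf(hist: DecayHistogram, shift: float) -> np.ndarray:
    t = hist.times
    irf = np.interp(t - shift, t, hist.irf_counts, left=0.0, right=0.0)
    s = irf.sum()
    return irf / s if s > 0 else irf


class TcspcDecayModel:
    """Iterative-reconvolution multiexponential TCSPC model.

    The model convolves the IRF histogram with Σ α_i exp(−t/τ_i) on the bin
    grid, with a fitted sub-bin time shift; weights are the Poisson ones,
    w_k = 1/max(counts_k, 1).  With ``reconvolve=False`` only the tail
    after the count maximum is fitted and the IRF is ignored.
    """

    def __init__(
        self,
        histogram: DecayHistogram,
        n_components: int,
        reconvolve: bool = True,
    ):
        if not 1 <= n_components <= 4:
            raise InputError("n_components must be in 1..4")
        if histogram.counts.max() < 1000:
            warnings.warn(
                "peak counts below 1000; fit may be unreliable",
                stacklevel=2,
            )
        self.histogram = histogram
        self.n_components = n_components
        self.reconvolve = reconvolve

    # -- internals ---------------------------------------------------------

    def _basis(self, tau: np.ndarray, shift: float) -> np.ndarray:
        h = self.histogram
        t = h.times - h.times[0]
        decays = np.exp(-t[:, None] / tau[None, :])
        if not self.reconvolve:
            return decays
        irf = _shifted_irf(h, shift)
        basis = np.empty_like(decays)
        for i in range(tau.size):
            basis[:, i] = np.convolve(irf, decays[:, i])[: t.size]
        return basis

    def _solve_amplitudes(
        self, tau: np.ndarray, shift: float, w: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        basis = self._basis(tau, shift)
        c = self.histogram.counts
        alpha, _ = nnls(basis[mask] * w[mask, None], c[mask] * w[mask])
        return alpha, basis

    def _tail_tau_estimate(self) -> float:
        h = self.histogram
        c = h.counts
        peak = int(np.argmax(c))
        tail = slice(peak, None)
        tt, cc = h.times[tail], c[tail]
        ok = cc > max(cc.max() * 1e-3, 1.0)
        if ok.sum() < 5:
            return max((h.times[-1] - h.times[0]) / 5.0, h.bin_width)
        slope = np.polyfit(tt[ok], np.log(cc[ok]), 1)[0]
        if slope >= 0:
            return max((h.times[-1] - h.times[0]) / 5.0, h.bin_width)
        return -1.0 / slope

    def fit(self) -> MultiExpFitResult:
        h = self.histogram
        c = h.counts
        w = 1.0 / np.sqrt(np.maximum(c, 1.0))
        if self.reconvolve:
            mask = np.ones(c.size, dtype=bool)
        else:
            mask = np.arange(c.size) >= int(np.argmax(c))
        n = self.n_components
        tau_long = self._tail_tau_estimate()
        tau_short = max(2.0 * h.bin_width, tau_long / 500.0)
        inits = [np.geomspace(tau_short, tau_long, n)]
        if n > 1:
            inits.append(np.geomspace(tau_short * 3, tau_long * 1.5, n))
            inits.append(np.geomspace(tau_short / 2, tau_long * 0.7, n))

        def residuals(p):
            tau = np.exp(p[:n])
            shift = p[n] if self.reconvolve else 0.0
            alpha, basis = self._solve_amplitudes(tau, shift, w, mask)
            model = basis @ alpha
            return (model[mask] - c[mask]) * w[mask]

        best = None
        for tau0 in inits:
            p0 = np.concatenate(
                [np.log(tau0), [0.0] if self.reconvolve else []]
            )
            if not self.reconvolve:
                p0 = np.log(tau0)
            try:
                sol = least_squares(
                    residuals, p0, method="trf", max_nfev=400 * (n + 1)
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("TCSPC decay fit did not converge")

        tau = np.exp(best.x[:n])
        shift = float(best.x[n]) if self.reconvolve else 0.0
        alpha, basis = self._solve_amplitudes(tau, shift, w, mask)
        if np.all(alpha <= 0):
            raise FitError("TCSPC decay fit collapsed to zero amplitude")
        model = basis @ alpha

        order = np.argsort(tau)
        tau, alpha = tau[order], alpha[order]
        # amplitude floor: components that carry no intensity are dropped
        keep = alpha > alpha.max() * 1e-9
        tau, alpha = tau[keep], alpha[keep]
        if tau.size > 1 and np.any(tau[1:] / tau[:-1] < 1.2):
            warnings.warn(
                "adjacent lifetimes within 20 %: model may be "
                "over-parameterised",
                stacklevel=2,
            )
        f = alpha * tau
        f = f / f.sum()
        tau_av = float((f * tau).sum())
        dof = mask.sum() - (2 * tau.size + (1 if self.reconvolve else 0))
        chi2 = float(
            np.sum(((c[mask] - model[mask]) ** 2) / np.maximum(c[mask], 1.0))
            / max(dof, 1)
        )
        chi2_defined = chi2 > 1e-6  # ~0 only for noiseless synthetic data
        return MultiExpFitResult(
            n_components=int(tau.size),
            alpha=alpha,
            tau=tau,
            f=f,
            tau_av=tau_av,
            chi2_reduced=chi2,
            chi2_defined=chi2_defined,
            shift=shift,
            reconvolved=self.reconvolve,
            model_counts=model,
            histogram=h,
        )


def fit_decay(
    histogram: DecayHistogram, n_components: int, reconvolve: bool = True
) -> MultiExpFitResult:
    """Convenience wrapper around :class:`TcspcDecayModel`."""
    return TcspcDecayModel(histogram, n_components, reconvolve).fit()


def compare_component_counts(
    histogram: DecayHistogram,
    n_low: int = 2,
    n_high: int = 3,
    improvement: float = 0.05,
    reconvolve: bool = True,
) -> tuple[MultiExpFitResult, MultiExpFitResult, bool]:
    """Fit with two component counts; report whether the richer model is
    justified by a > ``improvement`` relative drop in reduced χ²."""
    low = fit_decay(histogram, n_low, reconvolve)
    high = fit_decay(histogram, n_high, reconvolve)
    justified = high.chi2_reduced < (1.0 - improvement) * low.chi2_reduced
    return low, high, justified


# ---------------------------------------------------------------------------
# Anisotropy decay
# ---------------------------------------------------------------------------


@dataclass
class AnisotropyDecayFit:
    """Spherical-rotor anisotropy decay fit r(t) = r0 exp(−t/θ)."""

    r0: float
    theta: float  # ns
    residual_rms: float

    def summary(self) -> str:
        return (
            "Anisotropy decay fit (spherical rotor)\n"
            "--------------------------------------\n"
            f"r0            : {self.r0:.4f}\n"
            f"theta         : {self.theta:.4f} ns\n"
            f"residual rms  : {self.residual_rms:.3e}"
        )


class AnisotropyDecayModel:
    """Least-squares fit of r(t) = r0 exp(−t/θ) to an anisotropy series."""

    def __init__(
        self,
        times: np.ndarray,
        r: np.ndarray,
        r0_max: float = R0_MAX_DEFAULT,
    ):
        self.times = np.asarray(times, dtype=float)
        self.r = np.asarray(r, dtype=float)
        if self.times.shape != self.r.shape or self.times.size < 5:
            raise InputError("anisotropy fit needs >= 5 matched points")
        if np.any(self.r > 1.0) or np.any(self.r <= -0.5):
            raise InputError("anisotropy values outside (-0.5, 1]")
        self.r0_max = r0_max

    def fit(self) -> AnisotropyDecayFit:
        t, r = self.times, self.r
        span = float(np.ptp(r))
        if span < 1e-4 * max(abs(r).max(), 1e-12):
            raise DegenerateDataError(
                "anisotropy is constant: theta unresolvable (infinite)"
            )
        pos = r > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            theta0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        else:
            theta0 = (t[-1] - t[0]) / 2.0
        theta0 = float(np.clip(theta0, 1e-6, 1e6))
        r00 = float(np.clip(r[0], 1e-6, self.r0_max))
        try:
            popt, _ = curve_fit(
                lambda tt, r0, th: r0 * np.exp(-tt / th),
                t,
                r,
                p0=[r00, theta0],
                bounds=([0.0, 1e-9], [self.r0_max, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError("anisotropy decay fit did not converge") from exc
        resid = r - popt[0] * np.exp(-t / popt[1])
        return AnisotropyDecayFit(
            r0=float(popt[0]),
            theta=float(popt[1]),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )


def fit_anisotropy_decay(
    times: np.ndarray, r: np.ndarray, r0_max: float = R0_MAX_DEFAULT
) -> AnisotropyDecayFit:
    """Convenience wrapper around :class:`AnisotropyDecayModel`."""
    return AnisotropyDecayModel(times, r, r0_max=r0_max).fit()


def perrin_rotational_time(tau_av: float, r0: float, r: float) -> float:
    """Perrin relation θ = τ_av / (r0/r − 1) for a spherical rotor."""
    if tau_av <= 0:
        raise InputError("tau_av must be positive")
    if not 0 < r < r0:
        raise InputError("Perrin relation requires 0 < r < r0")
    return tau_av / (r0 / r - 1.0)
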