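"""Synthetic-data generators with exact ground truth.

Every input class consumed by the analysis stages can be generated here
with known truth, so the whole pipeline is testable without instrument
data or downloads: LOV-like protein sequences with planted motifs and
halophilic composition bias, flavin-like vibronic absorption/emission
spectra, photocycle depletion traces, TCSPC decay histograms with a
Gaussian instrument response, polarized intensity quadruples, and toy
coordinate sets with planted burial and salt bridges.

All generators take an explicit integer seed and create one private
pseudo-random stream per call; identical arguments give byte-identical
outputs.  The toy structures are deliberately schematic (isolated residue
"islands" and an occluding atom shell rather than a folded domain): they
exist to make burial and bridge counts provable, not to look like real
proteins.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fluorescence import DecayHistogram, PolarizedIntensities
from .mining import MOTIF_LENGTH, SequenceRecord
from .photocycle import KineticTrace
from .spectra import Spectrum
from .structure import Atom, StructureModel

_GROUP_CODES = {"A": 1, "B": 2, "outlier": 3}

_BACKGROUND_AA = "ACDEFGHIKLMNPQRSTVWY"


def _halophilic_weights(acidic_fraction: float, arg_over_lys: bool) -> np.ndarray:
    """Sampling weights over the 20 residues with acidic/Arg bias."""
    if not 0.0 <= acidic_fraction <= 0.6:
        raise InputError("acidic_fraction must be in [0, 0.6]")
    w = {aa: 1.0 for aa in _BACKGROUND_AA}
    w["D"] = w["E"] = 0.0
    w["R"], w["K"] = (3.0, 1.0) if arg_over_lys else (1.0, 3.0)
    total = sum(w.values())
    rest_mass = 1.0 - acidic_fraction
    weights = np.array(
        [w[aa] / total * rest_mass for aa in _BACKGROUND_AA]
    )
    i_d = _BACKGROUND_AA.index("D")
    i_e = _BACKGROUND_AA.index("E")
    weights[i_d] = weights[i_e] = acidic_fraction / 2.0
    return weights / weights.sum()


def _motif_string(variant: str, rng: np.random.Generator) -> str:
    x = _BACKGROUND_AA[rng.integers(len(_BACKGROUND_AA))]
    c = "P" if variant == "cys_to_pro" else "C"
    f = "Y" if variant == "phe_to_tyr" else "F"
    if variant not in ("canonical", "cys_to_pro", "phe_to_tyr"):
        raise InputError(f"unknown motif variant {variant!r}")
    return f"G{x}N{c}R{f}LQG"


def gen_lov_sequences(
    n: int,
    group: str = "A",
    seed: int = 0,
    length: int = 120,
    motif_variant: str = "canonical",
    motif_start: int | None = None,
    acidic_target: float = 0.20,
    arg_over_lys: bool = True,
    divergence: float = 0.04,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """LOV-like domains of one phylogenetic group, with truth table.

    Sequences of a group derive from a common random ancestor (seeded by
    ``(seed, group)``, so groups called with the same seed stay distinct),
    each mutated at non-motif positions with probability ``divergence``.
    Every sequence carries the planted motif, the group marker at position
    43 (Arg in group B, Glu in group A) and the halophilic composition
    bias (acidic fraction near ``acidic_target``, Arg favoured over Lys).

    Returns (records, truth) where truth has one row per record with the
    motif start (1-based), variant class and group.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if group not in _GROUP_CODES:
        raise InputError(f"group must be one of {sorted(_GROUP_CODES)}")
    if length < MOTIF_LENGTH + 50:
        raise InputError("sequences shorter than 59 residues cannot hold "
                         "the motif and marker layout")
    rng_anc = np.random.default_rng([seed, _GROUP_CODES[group]])
    rng = np.random.default_rng([seed, _GROUP_CODES[group], 7919])

    # the non-motif fraction of positions compensates for the fixed motif
    n_fixed = MOTIF_LENGTH + 1  # motif + marker residue
    eff_acidic = min(acidic_target * length / (length - n_fixed), 0.6)
    weights = _halophilic_weights(eff_acidic, arg_over_lys)
    letters = np.array(list(_BACKGROUND_AA))

    if motif_start is None:
        motif_start = int(rng_anc.integers(46, length - MOTIF_LENGTH - 4))
    if not (motif_start > 43 or motif_start + MOTIF_LENGTH - 1 < 43):
        raise InputError("motif placement overlaps the group marker at 43")

    ancestor = rng_anc.choice(letters, size=length, p=weights)
    marker = {"A": "E", "B": "R", "outlier": "W"}[group]
    ancestor[42] = marker
    motif = _motif_string(motif_variant, rng_anc)
    ancestor[motif_start - 1 : motif_start - 1 + MOTIF_LENGTH] = list(motif)

    protected = set(range(motif_start - 1, motif_start - 1 + MOTIF_LENGTH))
    protected.add(42)
    records = []
    rows = []
    for i in range(n):
        seq = ancestor.copy()
        mutate = rng.random(length) < divergence
        for pos in np.flatnonzero(mutate):
            if pos in protected:
                continue
            seq[pos] = letters[rng.choice(len(letters), p=weights)]
        rec_id = f"lov_{group}_{i:03d}"
        records.append(
            SequenceRecord(
                id=rec_id,
                seq="".join(seq),
                description=f"synthetic {group}-group LOV domain",
            )
        )
        rows.append(
            {
                "record_id": rec_id,
                "group": group,
                "motif_start": motif_start,
                "variant_class": motif_variant,
                "length": length,
            }
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _gauss(w: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / sigma) ** 2)


#: dark-state vibronic band centers (nm): UVA double peak, S0->S1 shoulder,
#: main maximum and red shoulder
DARK_BAND_CENTERS = (350.0, 370.0, 422.0, 446.0, 472.0)
DARK_BAND_SIGMAS = (20.0, 20.0, 12.0, 12.0, 12.0)
DARK_BAND_AMPS = (0.38, 0.40, 0.30, 1.00, None)  # shoulder amp is solved


def _dark_band_sum(
    w: np.ndarray, shoulder_amp: float, amplitude: float
) -> np.ndarray:
    amps = list(DARK_BAND_AMPS[:-1]) + [shoulder_amp]
    out = np.zeros_like(w, dtype=float)
    for c, s, a in zip(DARK_BAND_CENTERS, DARK_BAND_SIGMAS, amps):
        out += a * _gauss(w, c, s)
    return amplitude * out


def _solve_shoulder_amp(target_ratio: float, amplitude: float) -> float:
    from scipy.optimize import brentq

    fine = np.arange(430.0, 460.0, 0.01)

    def ratio(x: float) -> float:
        spec = _dark_band_sum(fine, x, amplitude)
        a_max = spec.max()
        a_sh = _dark_band_sum(np.array([472.0]), x, amplitude)[0]
        return a_sh / a_max

    return brentq(lambda x: ratio(x) - target_ratio, 0.0, 5.0, xtol=1e-10)


def gen_flavin_spectra(
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    amplitude: float = 0.5,
    shoulder_ratio_target: float = 0.82,
    crossings: tuple[float, float] = (380.0, 409.0),
    depletion_446: float = 0.46,
    diff_sigma: float = 25.0,
    noise: float = 0.0,
) -> tuple[Spectrum, Spectrum, dict]:
    """Dark and lit flavin-like absorption spectra with planted truth.

    The dark state is a sum of Gaussian vibronic bands (UVA double peak at
    350/370 nm, S0->S1 system at 422/446/472 nm); the 472 nm shoulder
    amplitude is solved so the analytic A_sh/A_max equals
    ``shoulder_ratio_target``.  The lit state adds a photochromic
    difference term −k·(λ−λ1)(λ−λ2)·G(λ) with a strictly positive Gaussian
    envelope G, so the dark/lit pair crosses exactly at the two planted
    isosbestic wavelengths (gain between them, bleach outside — the shape
    of a 446→390 nm photoconversion).  ``depletion_446`` sets the lit/dark
    ratio remaining at 446 nm; negative far-UV tails of the lit state are
    clipped at zero.  Optional additive Gaussian noise (sd in AU).
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 550.0 + 0.25, 0.5)
    if not 0.0 < depletion_446 < 1.0:
        raise InputError("depletion_446 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sh_amp = _solve_shoulder_amp(shoulder_ratio_target, amplitude)
    dark_clean = _dark_band_sum(wavelengths, sh_amp, amplitude)

    lam1, lam2 = crossings
    mid = 0.5 * (lam1 + lam2)

    def diff_term(w):
        return -(w - lam1) * (w - lam2) * _gauss(w, mid, diff_sigma)

    dark_446 = _dark_band_sum(np.array([446.0]), sh_amp, amplitude)[0]
    denom = diff_term(np.array([446.0]))[0]
    # scale the difference term so lit(446) = depletion_446 * dark(446)
    k = (depletion_446 - 1.0) * dark_446 / denom
    lit_clean = np.clip(dark_clean + k * diff_term(wavelengths), 0.0, None)

    dark_vals = dark_clean + (
        rng.normal(0.0, noise, wavelengths.size) if noise > 0 else 0.0
    )
    lit_vals = lit_clean + (
        rng.normal(0.0, noise, wavelengths.size) if noise > 0 else 0.0
    )
    fine = np.arange(430.0, 460.0, 0.01)
    fine_dark = _dark_band_sum(fine, sh_amp, amplitude)
    truth = {
        "shoulder_ratio": float(
            _dark_band_sum(np.array([472.0]), sh_amp, amplitude)[0]
            / fine_dark.max()
        ),
        "lambda_max": float(fine[np.argmax(fine_dark)]),
        "crossings": [float(lam1), float(lam2)],
        "shoulder_amp": float(sh_amp),
        "depletion_446": float(depletion_446),
    }
    dark = Spectrum(wavelengths, dark_vals, {"state": "dark"})
    lit = Spectrum(wavelengths, lit_vals, {"state": "lit"})
    return dark, lit, truth


def gen_aromatic_spectrum(
    seed: int = 0,
    centers: tuple[float, ...] = (277.0, 283.0),
    amplitudes: tuple[float, ...] = (1.0, 0.8),
    sigmas: tuple[float, ...] = (2.0, 2.0),
    redshift: float = 0.0,
    wavelengths: np.ndarray | None = None,
    noise: float = 0.0,
) -> tuple[Spectrum, dict]:
    """Aromatic-window UV absorption: Gaussian Tyr/Trp bands, optional
    uniform redshift (nm) emulating a salt-series band migration."""
    if wavelengths is None:
        wavelengths = np.arange(250.0, 300.0 + 0.125, 0.25)
    rng = np.random.default_rng(seed)
    shifted = [c + redshift for c in centers]
    vals = np.zeros_like(wavelengths)
    for c, a, s in zip(shifted, amplitudes, sigmas):
        vals += a * _gauss(wavelengths, c, s)
    if noise > 0:
        vals = vals + rng.normal(0.0, noise, wavelengths.size)
    truth = {"band_centers": shifted}
    return Spectrum(wavelengths, vals, {"window": "aromatic"}), truth


def gen_emission_spectrum(
    seed: int = 0,
    center: float = 342.0,
    sigma: float = 25.0,
    amplitude: float = 1000.0,
    wavelengths: np.ndarray | None = None,
    noise: float = 0.0,
) -> tuple[Spectrum, dict]:
    """Single-band Gaussian emission spectrum with analytic peak/FWHM truth."""
    if wavelengths is None:
        wavelengths = np.arange(center - 120.0, center + 120.0 + 0.5, 1.0)
    rng = np.random.default_rng(seed)
    vals = amplitude * _gauss(wavelengths, center, sigma)
    if noise > 0:
        vals = vals + rng.normal(0.0, noise, wavelengths.size)
    truth = {"center": center, "fwhm": 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma}
    return Spectrum(wavelengths, vals, {"kind": "emission"}), truth


# ---------------------------------------------------------------------------
# Kinetics and decays
# ---------------------------------------------------------------------------


def gen_photocycle_trace(
    tau: float = 89.0,
    a0: float = 0.5,
    a_inf: float = 0.1,
    t_max: float = 600.0,
    dt: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
    monitor_nm: float = 446.0,
) -> tuple[KineticTrace, dict]:
    """Monoexponential photodepletion trace A(t) = A_inf + (A0−A_inf)e^{−t/τ}.

    ``noise`` is the additive Gaussian standard deviation in AU.  The truth
    carries τ and the analytic initial slope −(A0 − A_inf)/τ.
    """
    if tau <= 0:
        raise InputError("tau must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    a = a_inf + (a0 - a_inf) * np.exp(-t / tau)
    if noise > 0:
        a = a + rng.normal(0.0, noise, t.size)
    truth = {
        "tau": tau,
        "a0": a0,
        "a_inf": a_inf,
        "initial_slope": -(a0 - a_inf) / tau,
    }
    return KineticTrace(times=t, absorbance=a, monitor_nm=monitor_nm), truth


def gen_decay_histogram(
    tau: Sequence[float],
    f: Sequence[float] | None = None,
    alpha: Sequence[float] | None = None,
    irf_fwhm: float = 0.8,
    total_counts: float = 5e6,
    bin_width: float = 0.0125,
    n_bins: int = 2000,
    irf_t0: float = 2.0,
    irf_total: float = 1e6,
    poisson: bool = True,
    seed: int = 0,
    lambda_em: float = 500.0,
) -> tuple[DecayHistogram, dict]:
    """TCSPC histogram: Gaussian IRF convolved with Σ α_i e^{−t/τ_i}.

    Either fractional contributions ``f`` (α_i then taken ∝ f_i/τ_i) or raw
    amplitudes ``alpha`` may be given.  Bins are Poisson-sampled unless
    ``poisson`` is off (noiseless expectation counts).  An ``irf_fwhm`` of
    zero plants a single-bin δ response at ``irf_t0``.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0) or np.any(np.diff(tau_arr) < 0):
        raise InputError("tau must be positive and sorted ascending")
    if (f is None) == (alpha is None):
        raise InputError("give exactly one of f or alpha")
    if f is not None:
        f_arr = np.asarray(f, dtype=float)
        if f_arr.shape != tau_arr.shape or np.any(f_arr <= 0):
            raise InputError("f must be positive and match tau")
        f_arr = f_arr / f_arr.sum()
        alpha_arr = f_arr / tau_arr
    else:
        alpha_arr = np.asarray(alpha, dtype=float)
        if alpha_arr.shape != tau_arr.shape or np.any(alpha_arr <= 0):
            raise InputError("alpha must be positive and match tau")
    alpha_arr = alpha_arr / alpha_arr.sum()
    f_truth = alpha_arr * tau_arr
    f_truth = f_truth / f_truth.sum()

    rng = np.random.default_rng(seed)
    t = np.arange(n_bins) * bin_width
    if irf_fwhm > 0:
        sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        irf = np.exp(-0.5 * ((t - irf_t0) / sigma) ** 2)
    else:
        irf = np.zeros(n_bins)
        irf[int(round(irf_t0 / bin_width))] = 1.0
    irf_norm = irf / irf.sum()
    decay = (alpha_arr[None, :] * np.exp(-t[:, None] / tau_arr[None, :])).sum(
        axis=1
    )
    model = np.convolve(irf_norm, decay)[:n_bins]
    model = model * (total_counts / model.sum())
    counts = rng.poisson(model).astype(float) if poisson else model
    hist = DecayHistogram(
        times=t,
        counts=counts,
        irf_counts=irf / max(irf.max(), 1e-300) * irf_total,
        lambda_em=lambda_em,
    )
    truth = {
        "tau": tau_arr.tolist(),
        "alpha": alpha_arr.tolist(),
        "f": f_truth.tolist(),
        "tau_av": float((f_truth * tau_arr).sum()),
        "irf_fwhm": irf_fwhm,
    }
    return hist, truth


def gen_polarized(
    r_true: float = 0.28,
    total_intensity: float = 1e5,
    g_true: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[PolarizedIntensities, dict]:
    """Polarized intensity quadruple inverting the L-format anisotropy.

    I_VV and I_VH solve r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) at the given
    total I_VV + 2G·I_VH; I_HV = G·I_HH fixes the G factor.  ``noise`` is a
    multiplicative Gaussian fraction applied to every channel.
    """
    if not -0.5 < r_true <= 1.0:
        raise InputError("r_true must lie in (-0.5, 1]")
    if g_true <= 0 or total_intensity <= 0:
        raise InputError("g_true and total_intensity must be positive")
    rng = np.random.default_rng(seed)
    i_vv = total_intensity * (1.0 + 2.0 * r_true) / 3.0
    i_vh = total_intensity * (1.0 - r_true) / (3.0 * g_true)
    i_hh = total_intensity / 3.0
    i_hv = g_true * i_hh
    vals = np.array([i_vv, i_vh, i_hv, i_hh])
    if noise > 0:
        vals = vals * (1.0 + rng.normal(0.0, noise, 4))
        vals = np.clip(vals, 0.0, None)
    p = PolarizedIntensities(
        i_vv=vals[0], i_vh=vals[1], i_hv=vals[2], i_hh=vals[3]
    )
    return p, {"r": r_true, "g": g_true}


def gen_anisotropy_series(
    r0: float = 0.4,
    theta: float = 1.06,
    t_max: float = 8.0,
    dt: float = 0.05,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Anisotropy decay series r(t) = r0 e^{−t/θ} with additive noise."""
    if r0 <= 0 or theta <= 0:
        raise InputError("r0 and theta must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    r = r0 * np.exp(-t / theta)
    if noise > 0:
        r = r + rng.normal(0.0, noise * r0, t.size)
    return t, r, {"r0": r0, "theta": theta}


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

# Residue templates in island-local coordinates (Å).  The first charged
# atom of acidic templates sits at the local origin; basic templates place
# their key nitrogen at the local origin so bridge distances can be planted
# exactly along +x.
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.46, 0.0, 0.0)),
        ("C", "C", (2.0, 1.25, 0.0)),
        ("O", "O", (3.2, 1.35, 0.0)),
        ("CB", "C", (1.95, -0.77, 1.2)),
    ],
    "ASP": [
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (-1.25, 0.0, 0.0)),
        ("OD2", "O", (-1.85, -1.1, 0.0)),
        ("CB", "C", (-2.0, 1.1, 0.3)),
        ("CA", "C", (-3.5, 1.1, 0.3)),
        ("N", "N", (-4.1, 2.3, 0.5)),
        ("C", "C", (-4.2, -0.15, 0.5)),
        ("O", "O", (-5.4, -0.2, 0.5)),
    ],
    "GLU": [
        ("OE1", "O", (0.0, 0.0, 0.0)),
        ("CD", "C", (-1.25, 0.0, 0.0)),
        ("OE2", "O", (-1.85, -1.1, 0.0)),
        ("CG", "C", (-2.0, 1.1, 0.3)),
        ("CB", "C", (-3.5, 1.1, 0.3)),
        ("CA", "C", (-4.1, 2.3, 0.5)),
        ("N", "N", (-5.6, 2.3, 0.5)),
        ("C", "C", (-4.3, 3.6, 0.6)),
        ("O", "O", (-3.4, 4.4, 0.7)),
    ],
    "ARG": [
        ("NH1", "N", (0.0, 0.0, 0.0)),
        ("CZ", "C", (1.33, 0.0, 0.0)),
        ("NH2", "N", (2.0, 1.1, 0.0)),
        ("NE", "N", (2.0, -1.1, 0.0)),
        ("CD", "C", (3.45, -1.2, 0.0)),
        ("CG", "C", (4.1, -2.4, 0.4)),
        ("CB", "C", (5.6, -2.4, 0.4)),
        ("CA", "C", (6.2, -3.6, 0.6)),
        ("N", "N", (7.7, -3.6, 0.6)),
        ("C", "C", (6.3, -4.9, 0.8)),
        ("O", "O", (7.4, -5.4, 0.9)),
    ],
    "LYS": [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CE", "C", (1.49, 0.0, 0.0)),
        ("CD", "C", (2.0, 1.3, 0.2)),
        ("CG", "C", (3.5, 1.3, 0.2)),
        ("CB", "C", (4.1, 2.6, 0.4)),
        ("CA", "C", (5.6, 2.6, 0.4)),
        ("N", "N", (6.2, 3.8, 0.6)),
        ("C", "C", (6.3, 1.35, 0.5)),
        ("O", "O", (7.5, 1.3, 0.5)),
    ],
}

_ISLAND_SPACING = 30.0
_SHELL_RADIUS = 5.8
_SHELL_POINTS = 110


def _island_origins() -> "itertools.count":
    """Endless well-separated island anchor points on a coarse 3D grid."""

    def gen():
        for i in itertools.count():
            # unfold the linear index onto a 3D grid
            x, rest = i % 8, i // 8
            y, z = rest % 8, rest // 8
            yield np.array(
                [x * _ISLAND_SPACING, y * _ISLAND_SPACING, z * _ISLAND_SPACING]
            )

    return gen()


def _sphere_shell(center: np.ndarray, radius: float, n: int) -> list[np.ndarray]:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    ) * radius
    return [center + p for p in pts]


def gen_toy_structure(
    n_bridges: int = 0,
    bridge_distance: float = 3.5,
    bridge_basic: str = "ARG",
    n_exposed_asp: int = 0,
    n_exposed_glu: int = 0,
    n_exposed_arg: int = 0,
    n_exposed_lys: int = 0,
    n_exposed_ala: int = 0,
    include_buried_core: bool = False,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Toy coordinate set with exactly known bridges and burial.

    Geometry is a set of residue "islands" 30 Å apart (no cross-island
    contacts).  A bridge island holds one Asp and one Arg/Lys whose closest
    charged-atom pair sits exactly at ``bridge_distance``; an exposed
    island holds one isolated, fully accessible residue.  The optional
    buried core is an alanine encased in an occluding carbon shell, giving
    a residue with near-zero accessibility.  The truth dict lists bridge
    pairs, the exposed and buried residue keys and the exposed D+E count.
    """
    if bridge_distance <= 0:
        raise InputError("bridge_distance must be positive")
    if bridge_basic not in ("ARG", "LYS"):
        raise InputError("bridge_basic must be ARG or LYS")
    origins = _island_origins()
    atoms: list[Atom] = []
    serial = 0
    resnum = 0
    truth_bridges = []
    exposed_keys: list[tuple[str, int]] = []
    buried_keys: list[tuple[str, int]] = []

    def add_residue(
        name: str, origin: np.ndarray, offset: np.ndarray | None = None
    ) -> tuple[str, int]:
        nonlocal serial, resnum
        resnum += 1
        shift = origin if offset is None else origin + offset
        for atom_name, element, local in _TEMPLATES[name]:
            serial += 1
            pos = shift + np.array(local)
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    residue_name=name,
                    chain="A",
                    residue_number=resnum,
                    xyz=tuple(float(v) for v in pos),
                    element=element,
                )
            )
        return ("A", resnum)

    for _ in range(n_bridges):
        origin = next(origins)
        akey = add_residue("ASP", origin)
        # key basic nitrogen lands exactly bridge_distance along +x from OD1
        bkey = add_residue(
            bridge_basic, origin, offset=np.array([bridge_distance, 0.0, 0.0])
        )
        truth_bridges.append((akey, bkey, bridge_distance))
        exposed_keys.extend([akey, bkey])

    for name, count in (
        ("ASP", n_exposed_asp),
        ("GLU", n_exposed_glu),
        ("ARG", n_exposed_arg),
        ("LYS", n_exposed_lys),
        ("ALA", n_exposed_ala),
    ):
        for _ in range(count):
            exposed_keys.append(add_residue(name, next(origins)))

    occluder_keys: list[tuple[str, int]] = []
    if include_buried_core:
        origin = next(origins)
        core_key = add_residue("ALA", origin)
        buried_keys.append(core_key)
        # occluding shell: one glycine CA pseudo-residue per shell point,
        # dense enough that no probe-expanded core surface point survives
        for pos in _sphere_shell(
            origin + np.array([1.46, 0.0, 0.0]), _SHELL_RADIUS, _SHELL_POINTS
        ):
            serial += 1
            resnum += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name="CA",
                    residue_name="GLY",
                    chain="S",
                    residue_number=resnum,
                    xyz=tuple(float(v) for v in pos),
                    element="C",
                )
            )
            occluder_keys.append(("S", resnum))

    if not atoms:
        raise InputError("empty structure requested")
    model = StructureModel(atoms=atoms, id=f"toy_seed{seed}")
    n_acid_exposed = n_exposed_asp + n_exposed_glu + n_bridges
    truth = {
        "bridges": truth_bridges,
        "n_bridges": n_bridges,
        "exposed_residues": set(exposed_keys),
        "buried_residues": set(buried_keys),
        "occluder_residues": set(occluder_keys),
        "exposed_de": n_acid_exposed,
    }
    return model, truth
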