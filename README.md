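# lovkit

Analysis toolkit for **halo-adapted LOV photoreceptors** — blue-light
sensor domains of the Light-Oxygen-Voltage (PAS) family, here the archaeal,
halophilic kind that keeps photocycling in multi-molar salt.

It is written for the spectroscopist or structural bioinformatician who has
(i) candidate protein sequences, (ii) predicted 3D models, and (iii)
UV-vis / fluorescence data for an expressed domain, and wants the complete
desk-side analysis chain as reproducible, tested code rather than a mix of
vendor software and spreadsheets.

## What it computes

**Sequence mining** (`lovkit.mining`) — scan for the superconserved LOV
motif `G-x-N-C-R-F-L-Q-G` (tolerating the natural C→P and F→Y variants),
score user-supplied conserved alignment columns, build p-distance matrices
and group candidates with a Saitou–Nei neighbor-joining tree (newick out).

**Halo-adaptation profile** (`lovkit.structure`) — residue composition,
Shrake–Rupley solvent-accessible surface area (fixed 960-point sphere set,
1.4 Å probe), surface exposure at a ≥ 10 % relative-accessibility cutoff
(theoretical max-ASA reference scale), and a salt-bridge census
(Asp/Glu carboxylate O to Arg/Lys/His side-chain N within 4.0 Å). Together
these quantify the halophilic signature: surface D/E enrichment, Arg-over-Lys
bias, dense ionic networks.

**Spectral analysis** (`lovkit.spectra`) — 9-point, 3rd-order
Savitzky–Golay second-derivative spectroscopy refined by cubic spline to a
0.01–0.02 nm grid; Tyr/Trp minima tracking in the 265–285 nm window; the
flavin vibronic shoulder ratio A_sh/A_max (472 nm vs 440–450 nm maximum);
isosbestic points of dark/lit spectrum pairs; emission peak and FWHM.

**Photocycle kinetics** (`lovkit.photocycle`) — the dark state (446 nm)
depletes under blue light as the cysteinyl–flavin adduct (390 nm) forms:

    A(t)   = A_inf + (A0 − A_inf) · exp(−t/τ)
    Φ_for  = (|dA/dt|_(t=0) / (Δε · l)) / q_np          (formation yield)
    %rec   = 100 · Abs(t_i) / Abs(t_0)                   (thermal recovery)
    ε_bound = (A_native / A_released) · ε_free(FMN, 12,200 M⁻¹cm⁻¹)

**Fluorescence dynamics** (`lovkit.fluorescence`) — L-format steady-state
anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with G = I_HV/I_HH;
relative fluorescence quantum yield against free FMN (Φ_ref = 0.26); TCSPC
multiexponential reconvolution fitting of I(t) = Σ αᵢ exp(−t/τᵢ) with
Poisson weights and a fitted IRF shift (amplitudes solved by nonnegative
least squares at each step — variable projection); fractional contributions
fᵢ = αᵢτᵢ/Σαⱼτⱼ, average lifetime τ_av = Σ fᵢτᵢ; anisotropy decay
r(t) = r₀ exp(−t/θ) and the Perrin relation θ = τ_av/(r₀/r − 1).

**Synthetic data** (`lovkit.simulate`) — seeded generators with exact
ground truth for every input class (sequences with planted motifs and
composition bias, vibronic band spectra with planted shoulder ratios and
isosbestic points, depletion traces, TCSPC histograms, polarized
intensities, toy coordinate sets with planted burial and bridges), so the
whole pipeline is testable offline.

Curve-fitting stages follow the model/results idiom: build
`PhotodepletionModel(trace)`, `TcspcDecayModel(hist, n)` or
`AnisotropyDecayModel(t, r)`, call `.fit()`, and read estimates,
uncertainties and `summary()` off the results object.

## Worked example

Simulate a wild-type-like photodepletion trace (τ = 89 s, monitored at
446 nm, mild noise) whose initial rate encodes a formation yield of 0.49,
fit it, and close the loop through the quantum-yield pipeline:

```python
import lovkit as lk
from lovkit.simulate import gen_photocycle_trace

slope = 0.49 * 1e-7 * 7640.0            # Phi * q_np * delta_eps * path
trace, truth = gen_photocycle_trace(
    tau=89.0, a0=0.1 + slope * 89.0, a_inf=0.1, noise=1.7e-4, seed=42,
)
fit = lk.fit_monoexponential(trace)
print(fit.summary())
qy = lk.quantum_yield_formation(fit, q_np=1e-7, delta_epsilon=7640.0)
print(f"Phi_for = {qy.phi_for:.3f}")
```

```
Monoexponential photodepletion fit
----------------------------------
monitor wavelength  : 446.0 nm
n points            : 301
A0                  : 0.13333 AU
A_inf               : 0.09999 AU
tau                 : 88.976 +/- 0.231 s
initial slope dA/dt : -3.7463e-04 AU/s
residual rms        : 1.585e-04 AU
Phi_for = 0.490
```

The fitted depletion time constant (88.98 s) recovers the planted 89 s, and
the initial slope, divided by Δε·l and the photon flux, returns the planted
formation quantum yield. The same closure works for the lifetime
arithmetic: with fractional contributions (52 %, 9.7 %, 38.3 %) and
components (0.05, 1.2, 3.37) ns, `lk.average_lifetime` gives
τ_av = 1.433 ns.

A command-line layer mirrors the library
(`lovkit mine|profile|spectra|photocycle|fluor|simulate`); every run writes
a provenance manifest (inputs, parameters, SHA-256 of outputs).

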