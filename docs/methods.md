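# Methods

This note records the models, defaults and numerical choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one convention exists.

## Motif scanning and grouping

The LOV-domain screen matches the nine-residue pattern
`G-x-N-[C/P]-R-[F/Y]-L-Q-G` (position 2 is unconstrained). The photoactive
cysteine at position 4 and the phenylalanine at position 6 are the two
positions where tolerated natural variants occur; a hit is classified
`canonical`, `cys_to_pro`, `phe_to_tyr`, or `other_tolerated` when both
vary at once. With variant tolerance off, only the strict pattern matches.
Coordinates are 1-based and refer to the unaligned sequence; overlapping
hits are all reported. `X` is accepted as an unknown residue but never
matches a constrained position.

The additional conserved-residue screen is deliberately configuration, not
code: the set of "other conserved" columns differs between published
alignments, so the caller supplies a column → allowed-residue-set table and
gets back matched/checked counts. Gap characters never match.

Distances are p-distances (mismatches over pairwise gap-free columns); a
pair with no comparable columns is an error rather than a silent 0 or 1.
Grouping is Saitou–Nei neighbor joining. Two conventions are fixed for
reproducibility: Q-criterion ties are broken by the lexicographically
smallest pair of cluster labels (a cluster's label is its smallest leaf
id), and negative branch-length estimates are clamped to zero with the
deficit moved to the sibling edge so the joined pair's path length is
conserved. On additive matrices the tree reproduces all leaf-to-leaf path
lengths to ≤ 1e-9 (verified in tests against brute-force quartet analysis
and an independent neighbor-joining implementation). Maximum-likelihood
tree building and bootstrap support are out of scope; alignment itself is
an input (any aligner's FASTA output works).

## Halo-adaptation profiling

Halophilic proteins show surface acidic enrichment, Arg-over-Lys bias and
dense salt-bridge networks. The profile quantifies these with explicit
criteria rather than reproducing any third-party tool's defaults:

* **SASA** — Shrake–Rupley with a deterministic golden-spiral sphere set,
  default 960 points/atom and a 1.4 Å water probe. Van der Waals radii are
  Bondi-style per element (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å);
  unknown elements raise unless a default radius is supplied. An isolated
  atom reproduces the analytic sphere 4π(r+p)² within the point-set
  discretisation (≪ 2 %); doubling the point count moves per-residue
  totals by < 1 %.
* **Exposure** — relative accessibility is residue SASA over a
  theoretical maximum-ASA reference (Tien-style theoretical values,
  shipped as a table and overridable); a residue is surface-exposed at
  ≥ 10 % by default. Relative accessibilities above 1 can occur for
  highly unconstrained conformations and are reported as computed.
* **Salt bridges** — an Asp/Glu carboxylate oxygen (OD1/OD2, OE1/OE2)
  within 4.0 Å of a basic side-chain nitrogen (Arg NH1/NH2/NE, Lys NZ,
  His ND1/NE2). Histidine counts as basic by default (a flag excludes
  it). Each residue pair is reported once with its minimum charged-atom
  distance. Only ionic contacts are typed; π-stacking, π-cation and VDW
  interaction typologies are out of scope.

Because the published counts for specific proteins depend on the exact
coordinates of structure predictions and on other tools' accessibility
definitions, this package does not claim to reproduce any specific
published count — it fixes one reproducible definition and applies it
uniformly. PDB input is parsed with gemmi (first model, altloc blank/'A').

## Second-derivative spectroscopy

Second derivatives of the aromatic UV window resolve the tyrosine (~277 nm)
and tryptophan (~283 nm) contributions as negative minima; their redshift
under rising salt reports on aromatic burial. The pipeline is: 9-point,
3rd-order Savitzky–Golay second derivative on the (uniform) sampling grid;
half-window endpoints discarded; cubic-spline interpolation of the
derivative to a 0.01–0.02 nm grid (default 0.02). Differentiation precedes
spline refinement — the refinement sharpens minima *positions*, not the
derivative estimate. Non-uniformly sampled spectra are linearly resampled
to the median step first and flagged. Derivative values below a 1e-13
round-off floor are zeroed so flat or linear spectra do not sprout spurious
extrema, and candidate minima with depths below 1e-6 of the deepest
minimum in the window are discarded as interpolation ripple. Minima
positions are refined parabolically; the reported depth is the derivative
value at the minimum.

The flavin band shape is summarised by A_sh/A_max: the maximum is taken in
a 440–450 nm window, the shoulder read by linear interpolation at a fixed
472 nm (the vibronic shoulder position; overridable) rather than
re-detected per spectrum, so the ratio stays comparable across a salt
series even when the shoulder flattens. Isosbestic points are located as
sign changes of the difference of two spectra resampled to their common
grid, linearly interpolated between bracketing samples; identical spectra
return an empty, degenerate-flagged result. Emission bands report a
parabolically refined peak and a FWHM interpolated at half maximum on both
flanks, erroring when either flank never reaches half maximum.

## Photocycle kinetics

Photodepletion is fitted as A(t) = A_inf + (A0 − A_inf)·exp(−t/τ) by least
squares, initialised from a log-linear fit of the tail-subtracted signal.
Constant traces are rejected as degenerate. The formation quantum yield
divides the initial concentration-depletion rate |dA/dt|₀/(Δε·l) by the
volumetric photon flux q_np (einstein L⁻¹ s⁻¹, a calibrated input —
actinometry chemistry is out of scope). q_np is interpreted as the flux
delivered to the sample; an optional flag rescales it by the absorbed
fraction (1 − 10^−A0) for users whose calibration measured incident flux.
Yields above 1 are flagged, not clipped — they indicate inconsistent
calibration. The monitoring wavelength is a parameter (446 nm default, the
dark-state maximum; the recovery ratio uses the same wavelength). Δε
combination: Δε = ε_dark·(1 − ratio), with the ratio the lit/dark
absorbance at the monitoring wavelength after scaling both spectra to
equality at an isosbestic point; which isosbestic point to use is the
caller's choice and recorded in provenance.

## TCSPC fitting

The decay model is I(t) = Σ αᵢ exp(−t/τᵢ) (1–4 components) convolved with
the measured IRF on the histogram grid, with a fitted sub-bin time shift.
Weights are Poisson (1/max(counts,1) on squared residuals). Because the
amplitudes enter linearly, the fit is separable: the nonlinear search runs
over {log τᵢ, shift} (scipy trust-region least squares, three staggered
log-spaced initialisations seeded from a tail-slope estimate) and the
amplitudes are re-solved by nonnegative least squares at every step. This
variable-projection scheme is far more robust than a joint search and
cannot produce negative component amplitudes. Reported: τᵢ (ascending),
αᵢ, fᵢ, τ_av, reduced χ², shift. χ² is flagged undefined for noiseless
synthetic input (it is only meaningful for Poisson counts). Adjacent
lifetimes within 20 % of each other trigger an over-parameterisation
warning; a helper compares two component counts and reports whether the
richer model improves reduced χ² by more than 5 %. A tail-fit mode (from
the count maximum, no IRF) is available for quick looks.

Anisotropy decays use the spherical-rotor model r(t) = r₀ exp(−t/θ) with
r₀ bounded by the one-photon theoretical maximum 0.4 (configurable).
Constant anisotropy series are rejected as unresolvable (θ → ∞). Steady-
state anisotropy uses the L-format with the instrumental G factor; band
averages default to ±5 nm windows around the 500 and 520 nm detection
wavelengths.

## Synthetic data: what it emulates, what it does not

Generators are seeded (`numpy.random.default_rng`, one private stream per
call) and byte-reproducible. They emulate the *structure* of each data
class, not instrument physics:

* **Sequences** — ~120-residue domains from a per-group random ancestor,
  a planted motif (any variant), a group marker at position 43 (Glu in
  group A, Arg in group B), and halophilic composition bias (acidic
  fraction targeted on the non-fixed positions, default 0.20; Arg
  weighted 3:1 over Lys). Point mutations at 4 % per site give within-
  group divergence an order of magnitude below between-group divergence,
  so planted groups are recoverable by distance methods. Real selection,
  indels and phylogenetic rate variation are not modelled.
* **Spectra** — Gaussian vibronic bands (dark: 350/370 nm UVA pair,
  422/446/472 nm S₀→S₁ system; widths 12 nm main, 20 nm UVA, chosen to
  emulate the morphology of flavoprotein spectra, not fitted to any
  measurement). The 472 nm amplitude is solved so the analytic A_sh/A_max
  equals its target (default 0.82); the lit state adds a photochromic
  difference term with exact planted roots at the isosbestic wavelengths
  (default 380/409 nm) and a set residual fraction at 446 nm. True
  lineshapes are not Gaussian; tests that depend on lineshape use the
  generator's own analytic truth, which is exact by construction.
* **Kinetics/decays** — exact mono/multiexponentials plus additive
  Gaussian noise (traces) or per-bin Poisson sampling after convolution
  with a Gaussian IRF (histograms, default 0.8 ns FWHM, 12.5 ps bins,
  2000 bins). Amplitudes can be specified as fractional contributions
  (αᵢ ∝ fᵢ/τᵢ). Detector afterpulsing, background and IRF drift are not
  modelled.
* **Toy structures** — residue "islands" 30 Å apart on a coarse grid:
  bridge islands place one Asp and one Arg/Lys with the closest
  charged-atom pair at an exact planted distance; exposure islands hold
  isolated, fully accessible residues; the buried-core scenario encases
  an alanine in a 110-atom occluding carbon shell (5.8 Å radius — dense
  enough that no probe-expanded core surface point survives, verified in
  tests). These are deliberately schematic: burial and bridge counts are
  provable, but the geometry is nothing like a folded domain, so passing
  tests demonstrate the correctness of the metrics, not their behaviour
  on borderline, partially buried real-protein residues.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 50 replicate
depletion traces (301 points each), single and few-replicate TCSPC fits at
5×10⁶ counts, SASA on structures of order 10²–10³ atoms, and 24-sequence
tree reconstructions — sizes chosen so the full suite completes in well
under a minute on one core while keeping every statistical check
comfortably away from its tolerance. All stochastic tests fix their seeds;
the acceptance script derives every replicate seed from its single
`--seed` argument.

## Known limitations

* Exposure and bridge counts for real structure-prediction models depend
  on conformer choice; the package reports one model's numbers, it does
  not ensemble.
* The TCSPC fitter assumes a measured IRF on the same binning as the
  decay; it does not model wavelength-dependent IRF shift beyond the
  single fitted offset, and component uncertainties are not reported
  (replicate fits are the supported way to assess spread).
* The Perrin relation assumes a single spherical rotor and a single
  r₀; flexible or multi-domain emitters violate it, which is precisely
  the diagnostic use it serves.
* Statistical comparison across salt series is a plain mean ± sd over
  replicate spectra; no specific hypothesis test is prescribed.
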