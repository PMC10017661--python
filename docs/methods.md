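# Methods

This note documents the models, defaults and numerical choices behind
`ssoptools`, and what the synthetic validation does and does not show.

## Forward models

**Diffusion closed form.** The spatial-frequency-domain diffuse
reflectance of a semi-infinite homogeneous medium is evaluated with the
standard partial-current-boundary closed form (see README for the
formula), with `R_eff(n) = 0.0636n + 0.668 + 0.710/n − 1.440/n²`. The
tissue refractive index defaults to `n = 1.4`, the conventional
soft-tissue value; no measured value exists for the modelled instrument,
so it is a declared constant, not an inference. Analytic limits used as
tests: `R_d → 1` as `μa → 0` under planar illumination (the deficit
falls as `√μa`, so the 10⁻⁶ bound needs `μa ≲ 10⁻¹⁴ mm⁻¹`), and strict
decrease with `fx` everywhere.

A characterised artefact: the closed form is *not* strictly decreasing
in `μa` at the lowest reduced scattering (`μs′ < ~0.6 mm⁻¹`) combined
with `fx ≥ 0.2 mm⁻¹`, where `R_d` rises with `μa` by a few 10⁻⁵
(raising `μa` raises `μ_tr` and shrinks `μ_eff′/μ_tr` faster than `a′`
falls). This is outside the diffusion approximation's validity range
(`fx` approaching `μ_tr′`); the test suite asserts strict monotonicity
where it truly holds and bounds the corner violation instead of hiding
it.

**Monte-Carlo oracle.** A photon-packet simulation in the MCML lineage:
pencil beam at normal incidence, Henyey–Greenstein phase function with
`g = 0.9` and `μs = μs′/(1−g)`, implicit-capture weight absorption,
angle-resolved Fresnel reflection at the top surface (specular entry
loss handled analytically, consistent with crossed-polariser specular
rejection), Russian roulette below weight 10⁻⁴ with survival factor 10.
Roulette is bookkept with a compensating ledger — a survivor's weight
gain is debited from the absorbed tally — so reflected + absorbed equals
launched weight to float precision, not merely in expectation. Escaping
weight is binned radially (0.1 mm bins to 50 mm; overflow folds into the
last bin) and the order-0 Hankel transform `R_d(fx) = Σ R(ρ)J₀(2πfxρ)ΔA`
converts the profile to the frequency domain; at `fx = 0` this equals
the total diffuse reflected fraction exactly. A result is flagged
unresolved when fewer than ~8 bins cover one Bessel period. The kernel
is compiled with numba; seeds are explicit everywhere.

Validation: the matched-index, isotropic, albedo-0.9 configuration
reproduces the classical semi-infinite plane-albedo value 0.41334 within
MC noise, and `g = 0` similarity runs agree with `g = 0.9` at `fx = 0`.

**Measured MC-vs-diffusion envelope** (10⁵ photons, fixed seed): 1.7–2.4%
at `fx = 0` across the table ranges; at `fx = 0.2 mm⁻¹` the gap is
5–13% for `μs′ ≥ 1.75 mm⁻¹` but reaches ~16% around `μs′ ≈ 1–1.5 mm⁻¹`
(e.g. 15.5% at `μa = 0.01, μs′ = 1.1`). This exceeds the 15% agreement
envelope asserted in the validation suite at exactly one declared test
point, which is left failing deliberately: it is the well-known
transport-vs-diffusion error at `fx·l′ ≈ 0.2` that motivates Monte-Carlo
lookup tables, not an implementation defect, and the evaluation points
were not moved to mask it.

## Lookup table and inversion

The table spans `μa ∈ [0.005, 0.05] mm⁻¹` (log-spaced — absorption acts
multiplicatively) and `μs′ ∈ [0.5, 3] mm⁻¹` (linear), 64×64 nodes,
frequency pair `(0, 0.2) mm⁻¹`. Bilinear interpolation in
`(log μa, μs′)` reproduces the closed form off-grid to <1%. Construction
validates the node invariants (`0 < R_AC ≤ R_DC ≤ 1`, `R_DC` strictly
decreasing in `μa`) and invertibility (monotone `R_AC/R_DC` along grid
lines, with a small tolerance absorbing Monte-Carlo node noise);
violation raises a construction error. Tables serialise to HDF5 with
engine/seed/frequency provenance and reload bit-identically.

Inversion is nearest-node search in `(R_DC, R_AC)` (each channel
normalised by its table median to balance dynamic ranges — the intent of
normalising by a phantom prediction, without requiring one in the
inversion interface) followed by one Newton step on the node's
finite-difference Jacobian. This gives sub-grid accuracy (≤2% off-grid
round trips) without an iterative solver. Pixels whose refined
properties leave the grid, or whose forward-model residual exceeds 5%,
are masked out-of-LUT — never extrapolated, because extrapolated optical
properties silently corrupt StO₂ downstream.

## Demodulation

The 3-phase formulas are exact identities and serve as the reference.
The single-snapshot route filters each row (the pattern runs along image
columns; physical x = column × pitch, phase referenced to column 0):
Blackman-windowed FIR low-pass with cutoff `fx/2` for the DC channel, a
symmetric band `fx(1 ± 1/2)` for the AC channel, envelope via the
analytic signal. Filter support defaults to 6 pattern periods (205 taps
at the default pitch) — long enough that the stopband fully rejects the
carrier from the DC channel — and the resulting `edge_margin`
(half-support, 102 px) is reported on every map. Frames are
mirror-extended before convolution and before the envelope transform.
Cutoffs, window and support are configuration knobs; the defaults were
fixed by the SSOP-vs-3-phase agreement invariant (≤1% on flat scenes),
not per-dataset tuning. A learned demodulator could be substituted
behind the same interface.

## Scene simulator

The digital phantom emulates a two-wavelength (665/860 nm) bowel-
ischaemia acquisition: 16-bit frames, 1024×1280 default geometry at
0.1465 mm/px (15 cm / 1024 rows; square pixels, pattern along the
1280-px axis), Poisson shot noise plus Gaussian read noise (SD 2
counts), source level 30 000 counts, modulation depth 0.8. The bowel is
a horizontal band whose ends extend past the field, so its only sharp
tissue/background edges run parallel to the pattern axis; per-row
filtering then never smears the dark surround into the tissue. (A
shorter capsule is possible, but ends closer than the filter support to
the outer ROIs would add edge artefacts the modelled wide-field
instrument does not exhibit.) Off-tissue pixels get drape-like
absorption (0.25 mm⁻¹), far outside the table — they surface in the
out-of-LUT mask exactly as a dark surround does in practice.

StO₂ truth: three plateaus (ischaemic 0.3008, marginal 0.4567,
vascularised 0.4808 — the study conditions used as ground truth) with
logistic transitions of 5 mm 10–90% width centred 15 mm and 40 mm from
the loop centre. Five 1 cm² ROIs sit at 0, ±25, ±50 mm, each ≥2.5 mm
from the nearest transition — clearances chosen from the demodulation
filter's main-lobe width at design time. Total haemoglobin defaults to
60 µM with a seeded smooth 5% texture (StO₂ is invariant to tHb, so the
texture exercises realism without biasing truth); `μs′` defaults 1.3 /
1.0 mm⁻¹ at 665 / 860 nm; non-haemoglobin background absorption
0.001 mm⁻¹ avoids the zero-absorption degeneracy and is shared with the
unmixer so the absorption model and StO₂ unmixing are exact mutual
inverses (≤10⁻⁶).

Haemoglobin extinction coefficients are a packaged, versioned CSV
compiled after Prahl's published tabulation; all numeric expectations in
the tests reference the shipped table, so they are self-consistent
regardless of compilation choice. All unit conversion between extinction
(cm⁻¹/M), concentration (µM) and `μa` (mm⁻¹) lives in one function.

The study-table generator produces per-(animal, ROI, time) rows over
0–60 min: systemic lactate stays at baseline (1.2 ± 0.15 mmol/L) while
capillary lactate rises linearly with zone-dependent slope, calibrated
so pooled capillary-minus-systemic means are 4.80 / 1.03 / 0.75 mmol/L
(ischaemic / marginal / vascularised); StO₂ declines concurrently so the
lactate–StO₂ association is negative by construction. Park/Chiu
histology grades are drawn once per animal×ROI (histology is terminal)
from zone means 4.5 / 1.58 / 0.67 and replicated across time rows.
Normalisation defaults to the difference convention (the ratio is
retained as an option because the convention is not standardised);
statistics are the product-moment correlation (Spearman exposed),
pooled-variance t with a reported (never acted-on) KS normality check,
and no multiple-testing correction.

## What the synthetic validation shows — and does not

Passing tests show the processing chain is mathematically correct and
self-consistent: exact 3-phase identities, SSOP within 1% of 3-phase on
flat scenes, ≤2% forward–inverse round trips, ~1.3% median recovery
error under the default noise model (well inside the 10% envelope), and
end-to-end ROI StO₂ recovery within 0.005 (noisy SSOP) of scene truth.
They do **not** show in-vivo accuracy: the scene is flat (no height or
curvature, hence no profilometry correction), its forward model is the
same family used for inversion (no model mismatch beyond the MC engine
option), chromophores beyond haemoglobin are absent, and motion,
specular breakthrough and inter-animal variability are not simulated.
The study-statistics results on synthetic cohorts demonstrate the
analysis shape, not biological effect sizes.

## Problem sizes

Default validation runs use reduced geometries chosen for desk-scale
reproducibility: 32–128 rows (rows are independent under per-row
demodulation, so row count only averages noise), full 1280-column width
where edge margins matter, 10⁵ photons for Monte-Carlo comparisons
(≈1–2% statistical error on reflectance), 120 phantoms for the accuracy
envelope, 1000 replicates for the type-I-error check.
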