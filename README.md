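# ssoptools

Spatial-frequency-domain imaging (SFDI) and single-snapshot imaging of
optical properties (SSOP) for tissue oximetry, at desk scale and fully
synthetic: forward models, structured-illumination simulation,
demodulation, phantom calibration, lookup-table inversion and
two-wavelength StO₂ unmixing, with the statistics used to validate an
intraoperative oximeter against perfusion biomarkers.

## Who this is for

Researchers building or evaluating SFDI/SSOP instruments (e.g.
structured-light oximeters for bowel-perfusion assessment) who need a
tested, reproducible reference implementation of the classical
processing chain and a digital phantom to exercise it — no camera, no
animal data.

## The method

SFDI projects sinusoidal light patterns of spatial frequency `fx` onto
tissue and measures how strongly diffuse reflectance is attenuated at
each frequency, separating absorption `μa` from reduced scattering
`μs′`. The classical workflow uses two frequencies (planar `fx = 0` and
patterned, here `fx = 0.2 mm⁻¹`) with three phase-shifted projections
each:

    M_DC = (I₁ + I₂ + I₃) / 3
    M_AC = (√2/3) · √[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]

SSOP replaces the six acquisitions with **one** patterned frame,
splitting each image row in the Fourier domain: a low-pass about 0
recovers `M_DC`, a band about ±fx followed by analytic-signal envelope
extraction recovers `M_AC` — at the cost of reduced lateral resolution
and edge artefacts, which this package measures and reports rather than
hides (every filtered map carries an `edge_margin`).

A reference phantom with known optical properties converts instrument
amplitudes into calibrated diffuse reflectance:

    R_X = (M_X,sample / M_X,reference) · R_X,model(phantom, fx_X),  X ∈ {DC, AC}

and a lookup table built with either the SFDI diffusion closed form

    R_d(fx) = 3Aa′ / [(μ_eff′/μ_tr + 1)(μ_eff′/μ_tr + 3A)]

(`μ_tr = μa + μs′`, `a′ = μs′/μ_tr`, `μ_eff′ = √(3μaμ_tr + (2πfx)²)`,
`A` from the refractive-index-dependent internal reflection) or with a
photon-packet Monte-Carlo engine (Henyey–Greenstein `g = 0.9`, Fresnel
surface, Russian roulette) is inverted per pixel to `(μa, μs′)`.
With absorption maps at 665 nm and 860 nm, Beer–Lambert unmixing gives
haemoglobin concentrations and

    StO₂ = c_HbO₂ / (c_HbO₂ + c_Hb).

## Worked example

`examples/bowel_sto2_pipeline.py` builds the ischaemic-bowel digital
phantom (central ischaemic zone, marginal and vascularised flanks, five
1 cm ROIs), simulates the two-wavelength acquisition and runs the whole
chain in both modes:

```
SFDI (3-phase reference, noiseless):
  ROI zone          truth   recovered  |err|
  1  ischaemic     0.3008  0.3008     0.0000
  2  marginal      0.4567  0.4565     0.0002
  3  vascularised  0.4808  0.4807     0.0001
  ...
SSOP (single snapshot, shot+read noise):
  1  ischaemic     0.3008  0.3015     0.0007
  2  marginal      0.4567  0.4571     0.0004
  3  vascularised  0.4808  0.4849     0.0041
  ...
```

The recovered per-ROI StO₂ means reproduce the scene truths — the
ischaemic centre sits ~15 StO₂ points below the perfused flanks, the
contrast the instrument is designed to image. The other examples show
the forward models (`forward_models.py`), single-frame recovery of
optical properties under noise (`single_snapshot_recovery.py`, ~0.2%
error at `μa = 0.0137`, `μs′ = 1.21`), and the study statistics
(`study_statistics.py`: lactate rises as StO₂ falls, r = −0.83 on the
synthetic cohort).

## Command line

```bash
ssop simulate  --config cfg.yaml --seed 5 --out run/      # frames + truth
ssop build-lut --config cfg.yaml --out lut.h5             # reflectance LUT
ssop process   --frames-dir run/frames --calibration-dir run/calibration \
               --lut lut.h5 --config cfg.yaml --out maps/ # StO2 + μ maps
ssop roi-stats --records study.csv --out stats/           # lactates, t, r
```

Every run writes its resolved configuration and a SHA-256 manifest next
to its outputs; exit codes are 0 (ok), 2 (configuration error), 3 (data
error).

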