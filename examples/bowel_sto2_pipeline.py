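"""Full oximetry pipeline on the ischaemic-bowel digital phantom.

Builds the synthetic bowel scene (central ischaemic zone, marginal and
vascularised flanks, five 1 cm ROIs), simulates the two-wavelength
(665/860 nm) structured-illumination acquisition with noise, and runs
demodulation -> calibration -> lookup-table inversion -> haemoglobin
unmixing for both processing routes, printing per-ROI StO2 against the
scene truth.
"""

from ssoptools import build_lut, make_bowel_scene
from ssoptools.pipeline import process_scene

scene = make_bowel_scene(shape=(128, 1280), seed=1)
lut = build_lut()
truth = {1: 0.3008, 2: 0.4567, 3: 0.4808, 4: 0.4567, 5: 0.4808}
zone = {1: "ischaemic", 2: "marginal", 3: "vascularised",
        4: "marginal", 5: "vascularised"}

for mode, noise_note in (("sfdi", "3-phase reference, noiseless"),
                         ("ssop", "single snapshot, shot+read noise")):
    kwargs = {"noise": None, "seed": None} if mode == "sfdi" \
        else {"seed": 17}
    res = process_scene(scene, lut, mode=mode, **kwargs)
    print(f"\n{mode.upper()} ({noise_note}):")
    print("  ROI zone          truth   recovered  |err|")
    for _, row in res.roi_table.iterrows():
        roi = int(row["roi"])
        print(f"  {roi}  {zone[roi]:<13} {truth[roi]:.4f}  "
              f"{row['sto2_mean']:.4f}     {abs(row['sto2_mean'] - truth[roi]):.4f}")

print("\nStO2 means are computed over quality-valid ROI pixels only; the "
      "ischaemic centre sits ~15 StO2 points below the perfused flanks, "
      "the contrast the instrument is built to image.")
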