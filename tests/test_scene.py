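"""Scene simulator: geometry, rendering identities, noise model, study."""

import numpy as np
import pytest

from ssoptools import NoiseModel, PatternSpec, diffusion_rd, \
    make_bowel_scene, render_calibration_set, render_frame, scene_to_mu_a, \
    simulate_study, unmix_sto2
from ssoptools.oximetry import ExtinctionTable
from ssoptools.scene import DEFAULT_PIXEL_PITCH, render_frames_from_props

TABLE = ExtinctionTable.default()


def test_roi_truth_means(bowel_scene):
    s = bowel_scene
    assert s.sto2_map[s.roi_masks == 1].mean() == pytest.approx(
        0.3008, abs=1e-3)
    for roi in (2, 4):
        assert s.sto2_map[s.roi_masks == roi].mean() == pytest.approx(
            0.4567, abs=1e-3)
    for roi in (3, 5):
        assert s.sto2_map[s.roi_masks == roi].mean() == pytest.approx(
            0.4808, abs=1e-3)
    # five disjoint labelled ROIs
    assert sorted(np.unique(s.roi_masks)) == [0, 1, 2, 3, 4, 5]


def test_zero_gradient_gives_piecewise_constant_masks():
    s = make_bowel_scene(shape=(128, 1280), gradient_width=0.0, seed=0)
    for roi, truth in ((1, 0.3008), (2, 0.4567), (3, 0.4808)):
        vals = s.sto2_map[s.roi_masks == roi]
        assert np.ptp(vals) == 0.0
        assert vals[0] == pytest.approx(truth, abs=1e-12)


def test_scene_determinism_and_texture_seed():
    a = make_bowel_scene(shape=(96, 1280), seed=3)
    b = make_bowel_scene(shape=(96, 1280), seed=3)
    c = make_bowel_scene(shape=(96, 1280), seed=4)
    assert np.array_equal(a.thb_map, b.thb_map)
    assert np.array_equal(a.sto2_map, c.sto2_map)  # geometry deterministic
    assert np.array_equal(a.roi_masks, c.roi_masks)
    assert not np.array_equal(a.thb_map, c.thb_map)  # texture is seeded


def test_rois_must_fit_field():
    with pytest.raises(ValueError):
        make_bowel_scene(shape=(64, 256), seed=0)  # ~37 mm wide field


def test_scene_to_mu_a_inverse_pair(bowel_scene):
    mu1 = scene_to_mu_a(bowel_scene, 665.0, TABLE)
    mu2 = scene_to_mu_a(bowel_scene, 860.0, TABLE)
    res = unmix_sto2(mu1, mu2, TABLE, bowel_scene.background_mu_a)
    t = bowel_scene.tissue_mask
    assert np.max(np.abs(res.sto2[t] - bowel_scene.sto2_map[t])) <= 1e-6


def test_scene_to_mu_a_oxygenation_contrast(bowel_scene):
    # deoxygenated tissue absorbs more in the red
    lo = make_bowel_scene(shape=(128, 1280), roi_sto2=(0.0, 0.0, 0.0),
                          texture_amplitude=0.0, seed=0)
    hi = make_bowel_scene(shape=(128, 1280), roi_sto2=(1.0, 1.0, 1.0),
                          texture_amplitude=0.0, seed=0)
    assert scene_to_mu_a(lo, 665.0, TABLE)[lo.tissue_mask].mean() > \
        scene_to_mu_a(hi, 665.0, TABLE)[hi.tissue_mask].mean()
    with pytest.raises(KeyError):
        scene_to_mu_a(bowel_scene, 550.0, TABLE)


def test_planar_frame_equals_flat_field(bowel_scene):
    f_m0 = render_frame(bowel_scene, PatternSpec(fx=0.2, modulation_depth=0.0),
                        665.0, TABLE, noise=None)
    f_fx0 = render_frame(bowel_scene, PatternSpec(fx=0.0), 665.0, TABLE,
                         noise=None)
    assert np.allclose(f_m0.image, f_fx0.image, rtol=1e-12)


def test_homogeneous_frame_spectrum_has_only_dc_and_carrier():
    """Column-axis FFT of a noiseless homogeneous patterned frame is
    supported on the DC bin and the +/- fx bins only."""
    pitch = DEFAULT_PIXEL_PITCH
    cols = 1024
    # choose fx exactly on an FFT bin so leakage is zero
    k = 30
    fx = k / (cols * pitch)
    ma = np.full((4, cols), 0.0137)
    frame = render_frames_from_props(
        ma, np.full_like(ma, 1.21), PatternSpec(fx=fx, pixel_pitch=pitch),
        665.0, None, None)
    spec = np.abs(np.fft.fft(frame.image[0]))
    on_bins = {0, k, cols - k}
    off = np.array([i for i in range(cols) if i not in on_bins])
    assert spec[k] > 1e5
    assert np.max(spec[off]) <= 1e-6 * spec[0]


def test_calibration_set_planar_mean_matches_forward_model():
    out = render_calibration_set(fx=0.2, shape=(32, 64), noise=None)
    planar_665 = out[665.0][0][0]
    expected = 0.5 * planar_665.pattern.dc_level \
        * diffusion_rd(0.01, 1.1, fx=0.0)
    assert planar_665.image.mean() == pytest.approx(expected, rel=1e-12)
    # the two wavelengths differ exactly by the forward-model ratio
    planar_860 = out[860.0][0][0]
    ratio = diffusion_rd(0.02, 0.8, fx=0.0) / diffusion_rd(0.01, 1.1, fx=0.0)
    assert planar_860.image.mean() / planar_665.image.mean() == \
        pytest.approx(ratio, rel=1e-12)


def test_noise_model_sd_matches_shot_plus_read():
    out = render_calibration_set(fx=0.2, shape=(256, 256),
                                 noise=NoiseModel(read_sd=2.0), seed=10)
    frame = out[665.0][0][0]  # planar, flat field
    lam = 0.5 * frame.pattern.dc_level * diffusion_rd(0.01, 1.1, fx=0.0)
    expected_sd = np.hypot(np.sqrt(lam), 2.0)
    assert frame.image.std() == pytest.approx(expected_sd, rel=0.10)


def test_saturation_recorded_not_silently_clipped():
    ma = np.full((8, 64), 0.005)
    frame = render_frames_from_props(
        ma, np.full_like(ma, 3.0),
        PatternSpec(fx=0.0, dc_level=2.0e5), 665.0, NoiseModel(), seed=0)
    assert frame.noise_meta["n_saturated"] > 0
    assert frame.image.max() <= 2**16 - 1


def test_nyquist_violation_rejected():
    with pytest.raises(ValueError):
        PatternSpec(fx=4.0, pixel_pitch=0.15)


# ---------------------------------------------------------------------------
# study generator
# ---------------------------------------------------------------------------


def test_study_table_shape_and_ranges():
    df = simulate_study(seed=0)
    assert len(df) == 6 * 5 * 5  # animals x ROIs x time points
    assert df["capillary_lactate"].min() > 0
    assert df["systemic_lactate"].min() > 0
    assert df["park_chiu"].between(0, 8).all()
    assert df["sto2_measured"].between(0, 1).all()


def test_study_determinism():
    a = simulate_study(seed=12)
    b = simulate_study(seed=12)
    assert a.equals(b)


def test_study_default_ischaemic_lactate_level():
    """Pooled capillary-minus-systemic lactate in the ischaemic ROI sits
    near the 4.8 mmol/L study condition."""
    df = simulate_study(n_animals=24, seed=2)  # more animals: tighter mean
    isch = df[df["roi"] == 1]
    norm = isch["capillary_lactate"] - isch["systemic_lactate"]
    assert norm.mean() == pytest.approx(4.804, abs=0.6)


def test_study_sto2_falls_as_lactate_rises():
    df = simulate_study(seed=3)
    isch = df[df["roi"] == 1].groupby("time_min")
    lact = isch["capillary_lactate"].mean()
    sto2 = isch["sto2_measured"].mean()
    assert lact.iloc[-1] > lact.iloc[0]
    assert sto2.iloc[-1] < sto2.iloc[0]
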