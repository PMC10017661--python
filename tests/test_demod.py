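"""Demodulation: 3-phase closed form vs least-squares oracle; SSOP vs SFDI."""

import numpy as np
import pytest

from ssoptools import FilterConfig, NoiseModel, OpticalProperties, \
    PatternSpec, sfdi_demodulate, ssop_demodulate
from ssoptools.scene import render_frames_from_props

PITCH = 150.0 / 1024.0
PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def _homog_acquisition(mu_a=0.0137, mu_s=1.21, fx=0.2, shape=(32, 1280),
                       noise=None, seed=None, dc_level=30000.0, m=0.8):
    ma = np.full(shape, mu_a)
    ms = np.full(shape, mu_s)
    pk = dict(dc_level=dc_level, modulation_depth=m, pixel_pitch=PITCH)
    planar, patterned = [], []
    for k, ph in enumerate(PHASES):
        sd = None if seed is None else seed + 2 * k
        planar.append(render_frames_from_props(
            ma, ms, PatternSpec(fx=0.0, phase=ph, **pk), 665.0, noise, sd))
        patterned.append(render_frames_from_props(
            ma, ms, PatternSpec(fx=fx, phase=ph, **pk), 665.0, noise,
            None if sd is None else sd + 1))
    return planar, patterned


def _lsq_amplitude_oracle(frames):
    """Brute-force per-pixel least-squares sinusoid fit.

    Model I_k = A + C cos(phi_k) + S sin(phi_k); the modulation amplitude
    is sqrt(C^2 + S^2).  Independent of the closed-form demodulation."""
    phases = np.array([f.pattern.phase for f in frames])
    design = np.column_stack(
        [np.ones_like(phases), np.cos(phases), np.sin(phases)])
    stack = np.stack([f.image for f in frames], axis=-1)  # (r, c, 3)
    flat = stack.reshape(-1, 3).T  # (3, npix)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    amp = np.hypot(coef[1], coef[2]).reshape(stack.shape[:2])
    return amp


def test_three_phase_exact_on_noiseless_frames():
    planar, patterned = _homog_acquisition(noise=None)
    maps = sfdi_demodulate(planar, patterned)
    # noiseless homogeneous: M_DC and M_AC are spatially constant and
    # equal to (I0/2) R_DC and (I0/2) m R_AC
    assert np.ptp(maps.m_dc) < 1e-9 * maps.m_dc.mean()
    assert np.ptp(maps.m_ac) < 1e-8 * maps.m_ac.mean()
    assert maps.edge_margin == 0
    # against the per-pixel least-squares oracle: machine precision
    oracle = _lsq_amplitude_oracle(patterned)
    assert np.max(np.abs(maps.m_ac - oracle) / oracle) < 1e-9


def test_three_phase_matches_lsq_oracle_on_noisy_frames():
    planar, patterned = _homog_acquisition(noise=NoiseModel(), seed=21)
    maps = sfdi_demodulate(planar, patterned)
    oracle = _lsq_amplitude_oracle(patterned)
    assert np.max(np.abs(maps.m_ac - oracle) / oracle) <= 1e-6


def test_zero_modulation_gives_zero_ac():
    planar, patterned = _homog_acquisition(noise=None, m=0.0)
    maps = sfdi_demodulate(planar, patterned)
    assert np.max(maps.m_ac) <= 1e-9 * maps.m_dc.mean()


def test_phase_sum_identity():
    # noiseless three-phase frames average to the planar frame
    planar, patterned = _homog_acquisition(noise=None)
    mean_img = sum(f.image for f in patterned) / 3.0
    assert np.allclose(mean_img, planar[0].image, rtol=1e-10)


def test_inconsistent_inputs_rejected():
    planar, patterned = _homog_acquisition(noise=None)
    with pytest.raises(ValueError):
        sfdi_demodulate(planar[:2], patterned)
    bad = list(patterned)
    bad[0] = render_frames_from_props(
        np.full((32, 1280), 0.0137), np.full((32, 1280), 1.21),
        PatternSpec(fx=0.2, phase=0.5, pixel_pitch=PITCH), 665.0, None, None)
    with pytest.raises(ValueError):
        sfdi_demodulate(planar, bad)


# ---------------------------------------------------------------------------
# single-snapshot route
# ---------------------------------------------------------------------------


def test_ssop_matches_three_phase_on_homogeneous_scene():
    """Noiseless flat scene: SSOP within 1% of the 3-phase reference in
    the central region for both channels."""
    planar, patterned = _homog_acquisition(noise=None)
    ref = sfdi_demodulate(planar, patterned)
    ss = ssop_demodulate(patterned[0])
    assert ss.edge_margin > 0
    c = np.s_[:, ss.edge_margin:-ss.edge_margin]
    for a, b in ((ss.m_dc, ref.m_dc), (ss.m_ac, ref.m_ac)):
        rel = np.abs(a[c] - b[c]) / b[c]
        assert np.max(rel) <= 0.01


def test_ssop_unpatterned_frame_has_no_ac():
    ma = np.full((16, 1280), 0.0137)
    frame = render_frames_from_props(
        ma, np.full_like(ma, 1.21),
        PatternSpec(fx=0.2, phase=0.0, modulation_depth=0.0,
                    pixel_pitch=PITCH), 665.0, None, None)
    maps = ssop_demodulate(frame)
    c = np.s_[:, maps.edge_margin:-maps.edge_margin]
    assert np.max(maps.m_ac[c]) <= 0.005 * np.mean(maps.m_dc[c])


def test_ssop_linearity_and_intensity_invariance():
    _, patterned = _homog_acquisition(noise=None)
    _, patterned2 = _homog_acquisition(noise=None, dc_level=60000.0)
    m1 = ssop_demodulate(patterned[0])
    m2 = ssop_demodulate(patterned2[0])
    c = np.s_[:, m1.edge_margin:-m1.edge_margin]
    # demodulation is linear: doubling I0 doubles both maps ...
    assert np.allclose(m2.m_dc[c], 2 * m1.m_dc[c], rtol=1e-9)
    assert np.allclose(m2.m_ac[c], 2 * m1.m_ac[c], rtol=1e-9)
    # ... so the modulation ratio M_AC/M_DC is intensity-invariant
    assert np.allclose(m2.m_ac[c] / m2.m_dc[c], m1.m_ac[c] / m1.m_dc[c],
                       rtol=1e-9)


def test_ssop_step_artefact_confined_to_edge_margin():
    """A sharp absorption step corrupts the SSOP maps only within the
    filter support around the step."""
    shape = (16, 1280)
    ma = np.full(shape, 0.01)
    ma[:, 640:] = 0.04  # step at column 640
    ms = np.full(shape, 1.21)
    frame = render_frames_from_props(
        ma, ms, PatternSpec(fx=0.2, pixel_pitch=PITCH), 665.0, None, None)
    planar, patterned = [], []
    for ph in PHASES:
        planar.append(render_frames_from_props(
            ma, ms, PatternSpec(fx=0.0, phase=ph, pixel_pitch=PITCH),
            665.0, None, None))
        patterned.append(render_frames_from_props(
            ma, ms, PatternSpec(fx=0.2, phase=ph, pixel_pitch=PITCH),
            665.0, None, None))
    ref = sfdi_demodulate(planar, patterned)
    ss = ssop_demodulate(frame)
    m = ss.edge_margin
    rel = np.abs(ss.m_ac - ref.m_ac) / ref.m_ac
    far = np.ones(shape[1], dtype=bool)
    far[640 - m:640 + m] = False  # near the step
    far[:m] = far[-m:] = False  # field edges
    assert np.max(rel[:, far]) <= 0.01
    assert np.max(rel[:, 640 - m:640 + m]) > 0.05  # artefact is real


def test_ssop_rejects_unresolvable_frequency():
    ma = np.full((8, 256), 0.01)
    frame = render_frames_from_props(
        ma, np.full_like(ma, 1.0),
        PatternSpec(fx=0.45, pixel_pitch=1.0), 665.0, None, None)
    with pytest.raises(ValueError):
        ssop_demodulate(frame)


def test_overlapping_filter_bands_rejected():
    with pytest.raises(ValueError):
        FilterConfig(dc_cutoff_frac=0.8, ac_halfwidth_frac=0.5)
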