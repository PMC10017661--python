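"""Phantom calibration and per-pixel LUT inversion."""

import numpy as np
import pytest

from ssoptools import CalibrationPhantom, OpticalProperties, calibrate, \
    diffusion_rd, invert_lut
from ssoptools.calibration import CalibrationError, DiffuseReflectanceMaps
from ssoptools.demod import ModulationMaps

FX_PAIR = (0.0, 0.2)


def _mod_maps(mu_a, mu_s, shape=(8, 16), i0=30000.0, m=0.8, wavelength=665.0):
    """Instrument-space maps a noiseless demodulation would produce."""
    r_dc = diffusion_rd(mu_a, mu_s, fx=0.0)
    r_ac = diffusion_rd(mu_a, mu_s, fx=0.2)
    return ModulationMaps(
        m_dc=np.full(shape, 0.5 * i0 * r_dc),
        m_ac=np.full(shape, 0.5 * i0 * m * r_ac),
        fx_pair=FX_PAIR, wavelength=wavelength)


def test_self_calibration_identity():
    phantom = CalibrationPhantom()
    maps = _mod_maps(0.01, 1.1)
    refl = calibrate(maps, maps, phantom, 665.0)
    assert np.allclose(refl.r_dc, diffusion_rd(0.01, 1.1, fx=0.0), rtol=1e-12)
    assert np.allclose(refl.r_ac, diffusion_rd(0.01, 1.1, fx=0.2), rtol=1e-12)
    assert refl.validity_mask.all()


def test_two_phantom_cross_check():
    """Calibrating phantom A against phantom B recovers A's model
    prediction, independent of instrument intensity/modulation."""
    phantom_b = CalibrationPhantom(
        props_per_wavelength={665.0: OpticalProperties(0.02, 0.9)})
    a = _mod_maps(0.035, 2.1, i0=41000.0, m=0.63)
    b = _mod_maps(0.02, 0.9, i0=41000.0, m=0.63)
    refl = calibrate(a, b, phantom_b, 665.0)
    assert np.max(np.abs(refl.r_dc - diffusion_rd(0.035, 2.1, fx=0.0))
                  / diffusion_rd(0.035, 2.1, fx=0.0)) <= 0.01
    assert np.max(np.abs(refl.r_ac - diffusion_rd(0.035, 2.1, fx=0.2))
                  / diffusion_rd(0.035, 2.1, fx=0.2)) <= 0.01


def test_missing_wavelength_raises():
    with pytest.raises(CalibrationError):
        calibrate(_mod_maps(0.01, 1.1), _mod_maps(0.01, 1.1),
                  CalibrationPhantom(), 700.0)


def test_reference_floor_masks_dead_pixels():
    sample = _mod_maps(0.01, 1.1)
    ref = _mod_maps(0.01, 1.1)
    ref.m_dc = ref.m_dc.copy()
    ref.m_dc[0, 0] = 0.0  # dead reference pixel
    refl = calibrate(sample, ref, CalibrationPhantom(), 665.0)
    assert not refl.validity_mask[0, 0]
    assert refl.validity_mask[1:].all()
    assert refl.meta["n_reference_floor_masked"] == 1


def _refl_maps(mu_a, mu_s, shape=(4, 4)):
    r_dc = np.full(shape, diffusion_rd(mu_a, mu_s, fx=0.0))
    r_ac = np.full(shape, diffusion_rd(mu_a, mu_s, fx=0.2))
    return DiffuseReflectanceMaps(
        r_dc=r_dc, r_ac=r_ac, wavelength=665.0, fx_pair=FX_PAIR,
        validity_mask=np.ones(shape, dtype=bool))


def test_node_exact_identity(default_lut):
    i, j = 20, 31
    ma = default_lut.mu_a_grid[i]
    ms = default_lut.mu_s_prime_grid[j]
    refl = DiffuseReflectanceMaps(
        r_dc=np.full((2, 2), default_lut.r_dc[i, j]),
        r_ac=np.full((2, 2), default_lut.r_ac[i, j]),
        wavelength=665.0, fx_pair=FX_PAIR,
        validity_mask=np.ones((2, 2), dtype=bool))
    op = invert_lut(refl, default_lut)
    assert np.allclose(op.mu_a_map, ma, rtol=1e-9)
    assert np.allclose(op.mu_s_prime_map, ms, rtol=1e-9)
    assert not op.out_of_lut_mask.any()


@pytest.mark.parametrize("mu_a,mu_s", [
    (0.0137, 1.21),  # off-grid interior point
    (0.0071, 2.63),
    (0.041, 0.77),
])
def test_forward_inverse_round_trip_off_grid(default_lut, mu_a, mu_s):
    op = invert_lut(_refl_maps(mu_a, mu_s), default_lut)
    assert not op.out_of_lut_mask.any()
    assert np.max(np.abs(op.mu_a_map - mu_a) / mu_a) <= 0.02
    assert np.max(np.abs(op.mu_s_prime_map - mu_s) / mu_s) <= 0.02


def test_nonphysical_reflectance_lands_in_mask(default_lut):
    refl = _refl_maps(0.0137, 1.21)
    refl.r_dc = refl.r_dc.copy()
    refl.r_dc[0, 0] = 1.5  # nonphysical
    refl.validity_mask = refl.validity_mask.copy()
    refl.validity_mask[0, 0] = False  # calibrate() would flag it
    op = invert_lut(refl, default_lut)
    assert op.out_of_lut_mask[0, 0]
    assert np.isnan(op.mu_a_map[0, 0])
    assert not op.out_of_lut_mask[1:, :].any()


def test_out_of_hull_reflectance_masked_not_extrapolated(default_lut):
    # a valid-looking R pair far outside the table's image set
    refl = _refl_maps(0.0137, 1.21)
    refl.r_dc = refl.r_dc.copy()
    refl.r_ac = refl.r_ac.copy()
    refl.r_dc[0, 0] = 0.95
    refl.r_ac[0, 0] = 0.1
    op = invert_lut(refl, default_lut)
    assert op.out_of_lut_mask[0, 0]
    assert np.isnan(op.mu_a_map[0, 0])


def test_inversion_deterministic(default_lut):
    refl = _refl_maps(0.0203, 1.87)
    a = invert_lut(refl, default_lut)
    b = invert_lut(refl, default_lut)
    assert np.array_equal(a.mu_a_map, b.mu_a_map)
    assert np.array_equal(a.mu_s_prime_map, b.mu_s_prime_map)


def test_empty_validity_mask_raises(default_lut):
    refl = _refl_maps(0.0137, 1.21)
    refl.validity_mask = np.zeros_like(refl.validity_mask)
    with pytest.raises(CalibrationError):
        invert_lut(refl, default_lut)
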