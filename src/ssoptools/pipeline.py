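"""End-to-end processing: frames -> optical properties -> StO2.

Glue shared by the command-line tool, the test suite and the
reproduction script.  The chain is

    demodulate (3-phase SFDI or single-snapshot SSOP)
    -> calibrate against the reference phantom
    -> invert the reflectance lookup table per pixel
    -> unmix the two wavelengths into StO2 / tHb
    -> summarise over ROIs
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (CalibrationPhantom, OpticalPropertyMaps, calibrate,
                          invert_lut)
from .demod import FilterConfig, ModulationMaps, sfdi_demodulate, \
    ssop_demodulate
from .lut import ReflectanceLUT
from .oximetry import (DEFAULT_BACKGROUND_MU_A, ExtinctionTable, StO2Map,
                       roi_summary, unmix_sto2)
from .scene import NoiseModel, PatternSpec, RawFrame, ScenePhantom, \
    render_calibration_set, render_frames_from_props, render_sfdi_set

__all__ = ["ProcessingResult", "demodulate_acquisition", "process_frames",
           "process_scene", "recover_homogeneous_phantom"]


@dataclass
class ProcessingResult:
    """Everything the pipeline produces for one acquisition."""

    op_maps: dict[float, OpticalPropertyMaps]
    sto2: StO2Map
    roi_table: pd.DataFrame | None = None
    attrition: dict = field(default_factory=dict)


def demodulate_acquisition(
    planar: list[RawFrame] | None,
    patterned: list[RawFrame],
    mode: str,
    filter_cfg: FilterConfig | None = None,
) -> ModulationMaps:
    """Demodulate one wavelength's frames in ``"sfdi"`` or ``"ssop"`` mode.

    SFDI needs three planar + three patterned frames; SSOP uses only the
    first patterned frame (its DC channel comes from the same frame).
    """
    if mode == "sfdi":
        if planar is None or len(planar) != 3 or len(patterned) != 3:
            raise ValueError("sfdi mode needs 3 planar + 3 patterned frames")
        return sfdi_demodulate(planar, patterned)
    if mode == "ssop":
        return ssop_demodulate(patterned[0], filter_cfg or FilterConfig())
    raise ValueError(f"unknown processing mode {mode!r}")


def process_frames(
    sample_frames: dict[float, tuple[list[RawFrame], list[RawFrame]]],
    reference_frames: dict[float, tuple[list[RawFrame], list[RawFrame]]],
    lut: ReflectanceLUT,
    phantom: CalibrationPhantom | None = None,
    *,
    mode: str = "ssop",
    filter_cfg: FilterConfig | None = None,
    extinction: ExtinctionTable | None = None,
    background_mu_a: float = DEFAULT_BACKGROUND_MU_A,
    roi_masks: np.ndarray | None = None,
) -> ProcessingResult:
    """Run the full pipeline on a two-wavelength acquisition.

    ``sample_frames`` / ``reference_frames`` map wavelength ->
    (planar frames, patterned frames), as produced by the scene module.
    """
    phantom = phantom or CalibrationPhantom()
    wavelengths = sorted(sample_frames)
    if len(wavelengths) != 2:
        raise ValueError("two wavelengths are required for oximetry")
    missing = [w for w in wavelengths if w not in reference_frames]
    if missing:
        raise ValueError(f"reference acquisition missing wavelengths "
                         f"{missing}")
    op_maps: dict[float, OpticalPropertyMaps] = {}
    attrition: dict = {}
    for wl in wavelengths:
        planar_s, patterned_s = sample_frames[wl]
        planar_r, patterned_r = reference_frames[wl]
        m_sample = demodulate_acquisition(planar_s, patterned_s, mode,
                                          filter_cfg)
        m_ref = demodulate_acquisition(planar_r, patterned_r, mode,
                                       filter_cfg)
        refl = calibrate(m_sample, m_ref, phantom, wl,
                         n_tissue=lut.n_tissue)
        op = invert_lut(refl, lut)
        op_maps[wl] = op
        attrition[wl] = {
            "reference_floor": refl.meta["n_reference_floor_masked"],
            "out_of_lut": op.meta["n_out_of_lut"],
            "edge_margin": refl.edge_margin,
        }
    wl_red, wl_nir = wavelengths
    sto2 = unmix_sto2(op_maps[wl_red].mu_a_map, op_maps[wl_nir].mu_a_map,
                      extinction, background_mu_a,
                      wavelengths=(wl_red, wl_nir))
    # propagate inversion failures into the oximetry quality mask
    sto2.quality_mask &= ~op_maps[wl_red].out_of_lut_mask
    sto2.quality_mask &= ~op_maps[wl_nir].out_of_lut_mask
    attrition["negative_concentration"] = int(
        (~sto2.quality_mask).sum())
    table = roi_summary(sto2, roi_masks) if roi_masks is not None else None
    return ProcessingResult(op_maps=op_maps, sto2=sto2, roi_table=table,
                            attrition=attrition)


def process_scene(
    scene: ScenePhantom,
    lut: ReflectanceLUT,
    *,
    mode: str = "ssop",
    fx: float | None = None,
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = 0,
    filter_cfg: FilterConfig | None = None,
    extinction: ExtinctionTable | None = None,
    phantom: CalibrationPhantom | None = None,
    dc_level: float = 30000.0,
    modulation_depth: float = 0.8,
) -> ProcessingResult:
    """Simulate an acquisition of ``scene`` and process it end to end.

    Renders sample and reference-phantom frames at both scene wavelengths
    (reference rendered with the same noise model), then runs
    :func:`process_frames`.  Convenience wrapper for tests, examples and
    reproduction runs.
    """
    fx = float(fx if fx is not None else lut.fx_pair[1])
    phantom = phantom or CalibrationPhantom()
    pk = dict(dc_level=dc_level, modulation_depth=modulation_depth,
              pixel_pitch=scene.pixel_pitch)
    wavelengths = sorted(scene.mu_s_prime_maps)
    sample: dict[float, tuple[list, list]] = {}
    for i, wl in enumerate(wavelengths):
        s = None if seed is None else int(seed) + 1000 * i
        planar, patterned = render_sfdi_set(
            scene, fx, wl, extinction, noise, s, pattern_kwargs=pk)
        sample[wl] = (planar, patterned)
    reference = render_calibration_set(
        {wl: phantom.properties(wl) for wl in wavelengths}, fx,
        scene.shape, noise,
        None if seed is None else int(seed) + 50_000,
        pattern_kwargs=pk)
    return process_frames(
        sample, reference, lut, phantom, mode=mode, filter_cfg=filter_cfg,
        extinction=extinction, roi_masks=scene.roi_masks)


def recover_homogeneous_phantom(
    mu_a: float,
    mu_s_prime: float,
    lut: ReflectanceLUT,
    *,
    wavelength: float = 665.0,
    shape: tuple[int, int] = (64, 512),
    fx: float | None = None,
    noise: NoiseModel | None = NoiseModel(),
    seed: int | None = 0,
    mode: str = "ssop",
    filter_cfg: FilterConfig | None = None,
    phantom: CalibrationPhantom | None = None,
    dc_level: float = 30000.0,
    modulation_depth: float = 0.8,
    pixel_pitch: float | None = None,
) -> tuple[OpticalPropertyMaps, int]:
    """Render a homogeneous slab, process one wavelength, return the
    recovered property maps and the demodulation edge margin.

    The workhorse of the accuracy-envelope evaluation: ground truth is
    (mu_a, mu_s'), the measurement is the central region of the returned
    maps.
    """
    from .scene import DEFAULT_PIXEL_PITCH

    fx = float(fx if fx is not None else lut.fx_pair[1])
    phantom = phantom or CalibrationPhantom()
    pitch = pixel_pitch or DEFAULT_PIXEL_PITCH
    pk = dict(dc_level=dc_level, modulation_depth=modulation_depth,
              pixel_pitch=pitch)
    props = phantom.properties(wavelength)
    mu_a_map = np.full(shape, float(mu_a))
    mu_s_map = np.full(shape, float(mu_s_prime))
    ref_a = np.full(shape, props.mu_a)
    ref_s = np.full(shape, props.mu_s_prime)

    def _acq(ma, ms, base_seed):
        phases = (0.0, 2 * np.pi / 3, 4 * np.pi / 3) if mode == "sfdi" \
            else (0.0,)
        planar, patterned = [], []
        for k, ph in enumerate(phases):
            sd = None if base_seed is None else base_seed + 2 * k
            planar.append(render_frames_from_props(
                ma, ms, PatternSpec(fx=0.0, phase=ph, **pk), wavelength,
                noise, sd))
            patterned.append(render_frames_from_props(
                ma, ms, PatternSpec(fx=fx, phase=ph, **pk), wavelength,
                noise, None if sd is None else sd + 1))
        if mode == "ssop":
            planar = planar * 3
            patterned = patterned * 3
        return planar, patterned

    planar_s, patterned_s = _acq(mu_a_map, mu_s_map,
                                 None if seed is None else int(seed))
    planar_r, patterned_r = _acq(ref_a, ref_s,
                                 None if seed is None else int(seed) + 77)
    m_sample = demodulate_acquisition(planar_s, patterned_s, mode, filter_cfg)
    m_ref = demodulate_acquisition(planar_r, patterned_r, mode, filter_cfg)
    refl = calibrate(m_sample, m_ref, phantom, wavelength,
                     n_tissue=lut.n_tissue)
    op = invert_lut(refl, lut)
    return op, m_sample.edge_margin
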