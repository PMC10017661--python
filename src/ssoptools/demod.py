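"""Demodulation of structured-illumination frames.

Two routes from camera frames to modulation-amplitude maps (M_DC, M_AC):

* ``sfdi_demodulate`` — the reference 3-phase route.  With three planar
  frames and three patterned frames at phases 0, 2pi/3, 4pi/3,

      M_DC = (I1 + I2 + I3) / 3                      (planar trio)
      M_AC = (sqrt(2)/3) sqrt[(I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2]

  recovers the per-pixel planar level and sinusoid amplitude exactly.

* ``ssop_demodulate`` — the single-snapshot route.  One patterned frame
  is filtered per row (the pattern runs along image columns): a
  Blackman-windowed low-pass around 0 yields M_DC, a band filter around
  +/- fx followed by analytic-signal envelope extraction yields M_AC.
  Filtering trades one acquisition for reduced lateral resolution and an
  ``edge_margin`` of diminished validity at the field borders.

Both produce amplitudes in camera counts; the shared calibration step
downstream cancels source intensity and modulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import firwin, hilbert

from .scene import RawFrame

__all__ = ["ModulationMaps", "FilterConfig", "sfdi_demodulate",
           "ssop_demodulate"]

THREE_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass
class ModulationMaps:
    """Demodulated per-pixel amplitudes, camera counts.

    ``edge_margin`` counts the pixels at each lateral field edge where a
    Fourier-filtered result is degraded (0 for the 3-phase route).
    """

    m_dc: np.ndarray
    m_ac: np.ndarray
    fx_pair: tuple[float, float]
    edge_margin: int = 0
    wavelength: float | None = None
    pixel_pitch: float | None = None
    meta: dict = field(default_factory=dict)

    def central_slice(self) -> tuple[slice, slice]:
        """Slices selecting the field with the edge margin removed."""
        m = self.edge_margin
        if m == 0:
            return np.s_[:, :]
        return np.s_[:, m:-m]


@dataclass(frozen=True)
class FilterConfig:
    """SSOP Fourier-filter configuration.

    Cutoffs are fractions of the pattern frequency: the DC low-pass cuts
    at ``dc_cutoff_frac * fx`` and the AC band spans
    ``fx * (1 +/- ac_halfwidth_frac)``.  ``support_periods`` sets the FIR
    length in pattern periods (longer = better band separation, larger
    edge margin).  Frames are mirror-extended before filtering.
    """

    dc_cutoff_frac: float = 0.5
    ac_halfwidth_frac: float = 0.5
    window: str = "blackman"
    support_periods: float = 6.0
    padding: str = "reflect"

    def __post_init__(self) -> None:
        if not 0 < self.dc_cutoff_frac <= 1:
            raise ValueError("dc_cutoff_frac must lie in (0, 1]")
        if not 0 < self.ac_halfwidth_frac < 1:
            raise ValueError("ac_halfwidth_frac must lie in (0, 1)")
        if self.dc_cutoff_frac > 1 - self.ac_halfwidth_frac:
            raise ValueError(
                "DC low-pass and AC band overlap: require "
                "dc_cutoff_frac <= 1 - ac_halfwidth_frac")
        if self.support_periods < 2:
            raise ValueError("support_periods must be >= 2")


def _check_frame_set(frames: Sequence[RawFrame], fx_expected: float,
                     phases: Sequence[float]) -> None:
    if len(frames) != 3:
        raise ValueError("exactly three frames are required")
    shp = frames[0].shape
    wl = frames[0].wavelength
    for f in frames:
        if f.shape != shp:
            raise ValueError("frame shapes differ")
        if f.wavelength != wl:
            raise ValueError("frame wavelengths differ")
        if not np.isclose(f.pattern.fx, fx_expected):
            raise ValueError(
                f"expected fx={fx_expected}, got {f.pattern.fx}")
    got = np.sort([f.pattern.phase % (2 * np.pi) for f in frames])
    want = np.sort(np.asarray(phases) % (2 * np.pi))
    if not np.allclose(got, want, atol=1e-9):
        raise ValueError(
            f"patterned phases must be {phases} (any order), got {got}")


def sfdi_demodulate(
    frames_dc: Sequence[RawFrame],
    frames_ac: Sequence[RawFrame],
) -> ModulationMaps:
    """Three-phase demodulation (the multi-frame reference route).

    Parameters
    ----------
    frames_dc : three planar frames (fx = 0).
    frames_ac : three patterned frames at phases 0, 2pi/3, 4pi/3.
    """
    if len(frames_dc) != 3 or len(frames_ac) != 3:
        raise ValueError("three planar and three patterned frames required")
    fx = frames_ac[0].pattern.fx
    if fx <= 0:
        raise ValueError("patterned frames must have fx > 0")
    _check_frame_set(frames_ac, fx, THREE_PHASES)
    for f in frames_dc:
        if not np.isclose(f.pattern.fx, 0.0):
            raise ValueError("planar frames must have fx = 0")
        if f.shape != frames_ac[0].shape \
                or f.wavelength != frames_ac[0].wavelength:
            raise ValueError("planar/patterned sets are inconsistent")
    i1, i2, i3 = (f.image.astype(float) for f in frames_ac)
    m_ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2)
    m_dc = sum(f.image.astype(float) for f in frames_dc) / 3.0
    return ModulationMaps(
        m_dc=m_dc, m_ac=m_ac, fx_pair=(0.0, fx), edge_margin=0,
        wavelength=frames_ac[0].wavelength,
        pixel_pitch=frames_ac[0].pattern.pixel_pitch,
        meta={"method": "sfdi-3phase"},
    )


def _design_kernels(fx: float, pitch: float, cfg: FilterConfig):
    fs = 1.0 / pitch  # samples per mm
    period_px = fs / fx
    numtaps = int(round(cfg.support_periods * period_px))
    numtaps += 1 - numtaps % 2  # odd
    lp = firwin(numtaps, cfg.dc_cutoff_frac * fx, window=cfg.window, fs=fs)
    band = (fx * (1.0 - cfg.ac_halfwidth_frac),
            fx * (1.0 + cfg.ac_halfwidth_frac))
    bp = firwin(numtaps, band, window=cfg.window, pass_zero=False, fs=fs)
    return lp, bp, numtaps


def ssop_demodulate(
    frame: RawFrame,
    cfg: FilterConfig = FilterConfig(),
) -> ModulationMaps:
    """Single-snapshot demodulation of one patterned frame.

    Each row is treated as a 1-D signal along the pattern axis.  The DC
    channel is the Blackman-windowed low-pass of the row; the AC channel
    is the magnitude of the analytic signal of the band-filtered row,
    which strips the carrier and leaves the local sinusoid amplitude.
    ``edge_margin`` is half the FIR support.

    Requires the pattern to be comfortably resolvable: at least 8 pixels
    per period (a quarter of Nyquist headroom).
    """
    fx = frame.pattern.fx
    pitch = frame.pattern.pixel_pitch
    if fx <= 0:
        raise ValueError("SSOP needs a patterned frame (fx > 0)")
    period_px = 1.0 / (fx * pitch)
    if period_px < 8.0:
        raise ValueError(
            f"fx={fx}/mm gives {period_px:.1f} px/period; need >= 8 "
            "for single-frame demodulation")
    lp, bp, numtaps = _design_kernels(fx, pitch, cfg)
    cols = frame.shape[1]
    if numtaps > cols:
        raise ValueError(
            f"filter support ({numtaps} px) exceeds frame width ({cols}); "
            "reduce support_periods or widen the frame")
    img = frame.image.astype(float)
    m_dc = convolve1d(img, lp, axis=1, mode=cfg.padding)
    band = convolve1d(img, bp, axis=1, mode=cfg.padding)
    # analytic-signal envelope; mirror-pad so FFT wrap-around stays out
    # of the reported field
    pad = numtaps // 2
    band_p = np.pad(band, ((0, 0), (pad, pad)), mode="reflect")
    env = np.abs(hilbert(band_p, axis=1))[:, pad:-pad]
    return ModulationMaps(
        m_dc=m_dc, m_ac=env, fx_pair=(0.0, fx), edge_margin=numtaps // 2,
        wavelength=frame.wavelength, pixel_pitch=pitch,
        meta={"method": "ssop", "numtaps": numtaps,
              "filter_cfg": cfg},
    )
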