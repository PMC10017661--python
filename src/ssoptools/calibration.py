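"""Phantom calibration and lookup-table inversion.

The demodulated amplitude maps are in instrument units (counts, folded
with source intensity, modulation depth and collection efficiency).  A
reference acquisition of a phantom with known optical properties cancels
all of that:

    R_X,sample = (M_X,sample / M_X,reference) * R_X,model(phantom, fx_X)

for X in {DC, AC}, where R_model comes from the forward model.  The
calibrated (R_DC, R_AC) pair is then inverted per pixel against the
lookup table: nearest table node in a channel-normalised metric followed
by one Newton step on the local cell, giving sub-grid accuracy without an
iterative solver.  Pixels outside the table's image set are masked, never
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .demod import ModulationMaps
from .lut import ReflectanceLUT
from .optics import OpticalProperties, diffusion_rd

__all__ = [
    "CalibrationPhantom",
    "DiffuseReflectanceMaps",
    "OpticalPropertyMaps",
    "CalibrationError",
    "calibrate",
    "invert_lut",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPhantom:
    """Reference phantom with known per-wavelength optical properties.

    The default mirrors the silicone calibration phantom of the modelled
    instrument: mu_a = 0.01, mu_s' = 1.1 mm^-1 at 665 nm; mu_a = 0.02,
    mu_s' = 0.8 mm^-1 at 860 nm.
    """

    props_per_wavelength: Mapping[float, OpticalProperties] = None
    description: str = "silicone reference phantom"

    def __post_init__(self) -> None:
        if self.props_per_wavelength is None:
            from .scene import REFERENCE_PHANTOM_PROPS

            object.__setattr__(
                self, "props_per_wavelength", dict(REFERENCE_PHANTOM_PROPS))

    def properties(self, wavelength: float) -> OpticalProperties:
        wl = float(wavelength)
        try:
            return self.props_per_wavelength[wl]
        except KeyError:
            raise CalibrationError(
                f"phantom has no optical properties at {wl} nm") from None


@dataclass
class DiffuseReflectanceMaps:
    """Calibrated per-pixel diffuse reflectance at the two frequencies.

    Nonphysical values (R > 1) are flagged invalid in ``validity_mask``
    rather than clipped.  ``validity_mask`` is True where trustworthy.
    """

    r_dc: np.ndarray
    r_ac: np.ndarray
    wavelength: float
    fx_pair: tuple[float, float]
    validity_mask: np.ndarray
    edge_margin: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class OpticalPropertyMaps:
    """Per-pixel recovered absorption / reduced scattering, mm^-1.

    ``out_of_lut_mask`` is True where inversion failed (input invalid,
    reflectance pair outside the table's image set, or residual too
    large); values there are NaN.
    """

    mu_a_map: np.ndarray
    mu_s_prime_map: np.ndarray
    wavelength: float
    out_of_lut_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def calibrate(
    sample: ModulationMaps,
    reference: ModulationMaps,
    phantom: CalibrationPhantom,
    wavelength: float | None = None,
    *,
    n_tissue: float = 1.4,
    forward=None,
    reference_floor: float = 0.01,
) -> DiffuseReflectanceMaps:
    """Turn instrument-space modulation maps into diffuse reflectance.

    Parameters
    ----------
    sample, reference : ModulationMaps
        Demodulated sample and phantom acquisitions; must share fx_pair,
        shape and wavelength, and must come from the same demodulation
        route so instrument factors cancel.
    phantom : CalibrationPhantom
        Known properties of the reference.
    forward : callable(mu_a, mu_s_prime, fx) -> R, optional
        Forward model for the phantom prediction (diffusion closed form
        by default).
    reference_floor : float
        Reference pixels below this fraction of the field median are
        masked (division stability).
    """
    wl = float(wavelength if wavelength is not None
               else (sample.wavelength or 0.0))
    if sample.wavelength is not None and reference.wavelength is not None \
            and sample.wavelength != reference.wavelength:
        raise CalibrationError("sample/reference wavelengths differ")
    if sample.m_dc.shape != reference.m_dc.shape:
        raise CalibrationError("sample/reference shapes differ")
    if not np.allclose(sample.fx_pair, reference.fx_pair):
        raise CalibrationError("sample/reference fx_pair differ")
    props = phantom.properties(wl)
    fx_dc, fx_ac = sample.fx_pair
    if forward is None:
        def forward(ma, ms, fx):
            return diffusion_rd(ma, ms, fx=fx, n_tissue=n_tissue)
    r_model_dc = float(forward(props.mu_a, props.mu_s_prime, fx_dc))
    r_model_ac = float(forward(props.mu_a, props.mu_s_prime, fx_ac))

    valid = np.ones(sample.m_dc.shape, dtype=bool)
    out = {}
    n_floor = 0
    for key, m_s, m_r, r_model in (
            ("r_dc", sample.m_dc, reference.m_dc, r_model_dc),
            ("r_ac", sample.m_ac, reference.m_ac, r_model_ac)):
        floor = reference_floor * np.median(m_r[m_r > 0]) \
            if np.any(m_r > 0) else np.inf
        bad_ref = ~(m_r > floor)
        n_floor += int(bad_ref.sum())
        valid &= ~bad_ref
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(bad_ref, np.nan, m_s / np.where(bad_ref, 1.0, m_r)
                         * r_model)
        out[key] = r
    # nonphysical reflectance: flag, do not clip
    with np.errstate(invalid="ignore"):
        nonphys = (out["r_dc"] > 1.0) | (out["r_ac"] > 1.0) \
            | (out["r_dc"] < 0) | (out["r_ac"] < 0)
    valid &= ~nonphys
    edge = max(sample.edge_margin, reference.edge_margin)
    return DiffuseReflectanceMaps(
        r_dc=out["r_dc"], r_ac=out["r_ac"], wavelength=wl,
        fx_pair=sample.fx_pair, validity_mask=valid, edge_margin=edge,
        meta={"n_reference_floor_masked": n_floor,
              "r_model": (r_model_dc, r_model_ac),
              "phantom": phantom.description},
    )


def _node_jacobians(lut: ReflectanceLUT):
    """Finite-difference d(R_DC, R_AC)/d(mu_a, mu_s') at every node."""
    ga, gs = lut.mu_a_grid, lut.mu_s_prime_grid
    d_dc_da = np.gradient(lut.r_dc, ga, axis=0)
    d_dc_ds = np.gradient(lut.r_dc, gs, axis=1)
    d_ac_da = np.gradient(lut.r_ac, ga, axis=0)
    d_ac_ds = np.gradient(lut.r_ac, gs, axis=1)
    jac = np.stack([
        np.stack([d_dc_da, d_dc_ds], axis=-1),
        np.stack([d_ac_da, d_ac_ds], axis=-1),
    ], axis=-2)  # shape (na, ns, 2, 2)
    return jac


def invert_lut(
    maps: DiffuseReflectanceMaps,
    lut: ReflectanceLUT,
    *,
    residual_tol: float = 0.05,
) -> OpticalPropertyMaps:
    """Per-pixel optical properties from calibrated reflectance maps.

    Nearest LUT node (Euclidean metric with each channel normalised by
    its table median) then one Newton step on the node's local Jacobian.
    A pixel is masked out-of-LUT when its input is invalid, the refined
    properties leave the grid ranges, or the forward-model residual at
    the refined point exceeds ``residual_tol`` (relative).
    """
    from scipy.spatial import cKDTree

    if not np.allclose(maps.fx_pair, lut.fx_pair):
        raise CalibrationError(
            f"maps fx_pair {maps.fx_pair} != LUT fx_pair {lut.fx_pair}")
    lut.validate()
    valid = maps.validity_mask & np.isfinite(maps.r_dc) \
        & np.isfinite(maps.r_ac)
    if not np.any(valid):
        raise CalibrationError("no valid pixels to invert")

    scale_dc = float(np.median(lut.r_dc))
    scale_ac = float(np.median(lut.r_ac))
    na, ns = lut.r_dc.shape
    nodes = np.column_stack([(lut.r_dc / scale_dc).ravel(),
                             (lut.r_ac / scale_ac).ravel()])
    tree = cKDTree(nodes)
    tgt = np.column_stack([maps.r_dc[valid] / scale_dc,
                           maps.r_ac[valid] / scale_ac])
    _, idx = tree.query(tgt, k=1)
    ia, is_ = np.unravel_index(idx, (na, ns))

    jac = _node_jacobians(lut)  # (na, ns, 2, 2)
    j_pix = jac[ia, is_]  # (npix, 2, 2)
    resid = np.column_stack([
        maps.r_dc[valid] - lut.r_dc[ia, is_],
        maps.r_ac[valid] - lut.r_ac[ia, is_],
    ])
    delta = np.linalg.solve(j_pix, resid[..., None])[..., 0]
    mu_a = lut.mu_a_grid[ia] + delta[:, 0]
    mu_s = lut.mu_s_prime_grid[is_] + delta[:, 1]

    in_range = (mu_a >= lut.mu_a_grid[0]) & (mu_a <= lut.mu_a_grid[-1]) \
        & (mu_s >= lut.mu_s_prime_grid[0]) & (mu_s <= lut.mu_s_prime_grid[-1])
    # forward residual check at the refined (clipped-in) point
    mu_a_c = np.clip(mu_a, lut.mu_a_grid[0], lut.mu_a_grid[-1])
    mu_s_c = np.clip(mu_s, lut.mu_s_prime_grid[0], lut.mu_s_prime_grid[-1])
    r_dc_hat, r_ac_hat = lut.interpolate(mu_a_c, mu_s_c)
    rel = np.hypot((r_dc_hat - maps.r_dc[valid]) / scale_dc,
                   (r_ac_hat - maps.r_ac[valid]) / scale_ac)
    ok = in_range & (rel <= residual_tol)

    mu_a_map = np.full(maps.r_dc.shape, np.nan)
    mu_s_map = np.full(maps.r_dc.shape, np.nan)
    flat_ok = np.zeros(maps.r_dc.shape, dtype=bool)
    vals_a = np.where(ok, mu_a, np.nan)
    vals_s = np.where(ok, mu_s, np.nan)
    mu_a_map[valid] = vals_a
    mu_s_map[valid] = vals_s
    flat_ok[valid] = ok
    return OpticalPropertyMaps(
        mu_a_map=mu_a_map,
        mu_s_prime_map=mu_s_map,
        wavelength=maps.wavelength,
        out_of_lut_mask=~flat_ok,
        meta={"n_out_of_lut": int((~flat_ok).sum()),
              "edge_margin": maps.edge_margin,
              "engine": lut.engine},
    )
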