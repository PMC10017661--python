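"""Lookup table mapping optical properties to (R_DC, R_AC) reflectance.

The table is the forward half of the inversion used by SFDI/SSOP
processing: for every (mu_a, mu_s') node it stores the diffuse reflectance
at the two working frequencies (planar fx_dc and patterned fx_ac).  The
inverse direction — per-pixel recovery of optical properties from measured
reflectance — lives in :mod:`ssoptools.calibration`.

Default grid: 64 x 64, log-spaced in mu_a over 0.005–0.05 mm^-1 and
linear in mu_s' over 0.5–3 mm^-1 (the ranges spanned by the tissue-like
training phantoms of the instrument this package models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import h5py
import numpy as np

from .mc import hankel_rd, mc_rd
from .optics import MediumContext, OpticalProperties, diffusion_rd

__all__ = ["ReflectanceLUT", "build_lut", "LUTConstructionError"]

DEFAULT_MU_A_RANGE = (0.005, 0.05)
DEFAULT_MU_S_PRIME_RANGE = (0.5, 3.0)
DEFAULT_FX_PAIR = (0.0, 0.2)


class LUTConstructionError(ValueError):
    """Raised when a grid cannot yield an invertible table."""


@dataclass
class ReflectanceLUT:
    """Forward table: (mu_a, mu_s') grid -> (R_DC, R_AC).

    ``r_dc`` and ``r_ac`` are 2-D arrays indexed ``[i_mu_a, i_mu_s_prime]``.
    """

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    fx_pair: tuple[float, float]
    r_dc: np.ndarray
    r_ac: np.ndarray
    n_tissue: float = 1.4
    engine: str = "diffusion"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, dtype=float)
        self.mu_s_prime_grid = np.asarray(self.mu_s_prime_grid, dtype=float)
        self.r_dc = np.asarray(self.r_dc, dtype=float)
        self.r_ac = np.asarray(self.r_ac, dtype=float)
        self.fx_pair = (float(self.fx_pair[0]), float(self.fx_pair[1]))

    # -- validation --------------------------------------------------------

    def validate(self, ratio_tol: float = 1e-3) -> None:
        """Check the type invariants; raise LUTConstructionError on failure.

        Invariants: ascending positive grids; 0 < R_AC <= R_DC <= 1 at
        every node; R_DC strictly decreasing in mu_a; R_AC/R_DC monotone
        along both grid directions (invertibility), with a small tolerance
        ``ratio_tol`` absorbing Monte-Carlo node noise.
        """
        for g, name in ((self.mu_a_grid, "mu_a"),
                        (self.mu_s_prime_grid, "mu_s_prime")):
            if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0) \
                    or np.any(g <= 0):
                raise LUTConstructionError(
                    f"{name} grid must be 1-D, ascending and positive")
        shape = (len(self.mu_a_grid), len(self.mu_s_prime_grid))
        if self.r_dc.shape != shape or self.r_ac.shape != shape:
            raise LUTConstructionError("table shape does not match grids")
        if not (np.all(np.isfinite(self.r_dc))
                and np.all(np.isfinite(self.r_ac))):
            raise LUTConstructionError("non-finite table values")
        if np.any(self.r_ac <= 0) or np.any(self.r_ac > self.r_dc) \
                or np.any(self.r_dc > 1):
            raise LUTConstructionError(
                "table must satisfy 0 < R_AC <= R_DC <= 1 at every node")
        if np.any(np.diff(self.r_dc, axis=0) >= 0):
            raise LUTConstructionError(
                "R_DC must be strictly decreasing in mu_a")
        ratio = self.r_ac / self.r_dc
        for axis in (0, 1):
            d = np.diff(ratio, axis=axis)
            if not (np.all(d >= -ratio_tol) or np.all(d <= ratio_tol)):
                raise LUTConstructionError(
                    "R_AC/R_DC ratio is non-monotone along the grid; "
                    "the grid is too coarse (or too noisy) to invert")

    # -- forward interpolation --------------------------------------------

    def interpolate(self, mu_a, mu_s_prime) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear (R_DC, R_AC) at arbitrary in-range properties.

        Interpolation is linear in (log mu_a, mu_s'), matching the grid
        spacing.  Out-of-range queries raise ValueError.
        """
        from scipy.interpolate import RegularGridInterpolator

        mu_a = np.asarray(mu_a, dtype=float)
        mu_s_prime = np.asarray(mu_s_prime, dtype=float)
        pts = np.stack(
            [np.log(mu_a).ravel(), mu_s_prime.ravel()], axis=-1)
        out = []
        for table in (self.r_dc, self.r_ac):
            f = RegularGridInterpolator(
                (np.log(self.mu_a_grid), self.mu_s_prime_grid), table,
                method="linear", bounds_error=True)
            out.append(f(pts).reshape(mu_a.shape))
        return out[0], out[1]

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Write the LUT to an HDF5 file; reloads bit-identically."""
        with h5py.File(path, "w") as f:
            f.create_dataset("mu_a_grid", data=self.mu_a_grid)
            f.create_dataset("mu_s_prime_grid", data=self.mu_s_prime_grid)
            f.create_dataset("r_dc", data=self.r_dc)
            f.create_dataset("r_ac", data=self.r_ac)
            f.attrs["fx_pair"] = np.asarray(self.fx_pair)
            f.attrs["n_tissue"] = self.n_tissue
            f.attrs["engine"] = self.engine
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "ReflectanceLUT":
        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(
                mu_a_grid=f["mu_a_grid"][:],
                mu_s_prime_grid=f["mu_s_prime_grid"][:],
                fx_pair=tuple(f.attrs["fx_pair"]),
                r_dc=f["r_dc"][:],
                r_ac=f["r_ac"][:],
                n_tissue=float(f.attrs["n_tissue"]),
                engine=str(f.attrs["engine"]),
                seed=None if seed == -1 else seed,
                meta=meta,
            )


def build_lut(
    mu_a_range: tuple[float, float] = DEFAULT_MU_A_RANGE,
    mu_s_prime_range: tuple[float, float] = DEFAULT_MU_S_PRIME_RANGE,
    grid_sizes: tuple[int, int] = (64, 64),
    fx_pair: tuple[float, float] = DEFAULT_FX_PAIR,
    ctx: MediumContext = MediumContext(),
    engine: Literal["diffusion", "monte-carlo"] = "diffusion",
    *,
    n_photons: int = 10_000,
    seed: int = 0,
) -> ReflectanceLUT:
    """Construct a ReflectanceLUT over the requested property ranges.

    mu_a nodes are log-spaced (absorption acts multiplicatively on
    reflectance), mu_s' nodes linear.  ``engine="diffusion"`` evaluates the
    closed form at every node; ``engine="monte-carlo"`` runs ``n_photons``
    packets per node and Hankel-transforms the radial profile at the two
    frequencies (per-node seeds are derived from ``seed``).

    Raises LUTConstructionError if the resulting table violates the
    invertibility invariants.
    """
    for rng, name in ((mu_a_range, "mu_a_range"),
                      (mu_s_prime_range, "mu_s_prime_range")):
        if not (0 < rng[0] < rng[1]) or not np.all(np.isfinite(rng)):
            raise LUTConstructionError(
                f"{name} must be positive and ordered, got {rng}")
    if not (0 <= fx_pair[0] < fx_pair[1]):
        raise LUTConstructionError("fx_pair must be ordered with fx_dc < fx_ac")
    n_a, n_s = int(grid_sizes[0]), int(grid_sizes[1])
    if n_a < 2 or n_s < 2:
        raise LUTConstructionError("grids need at least 2 nodes per axis")
    if engine not in ("diffusion", "monte-carlo"):
        raise ValueError(f"unknown engine {engine!r}")

    mu_a_grid = np.geomspace(mu_a_range[0], mu_a_range[1], n_a)
    mu_s_grid = np.linspace(mu_s_prime_range[0], mu_s_prime_range[1], n_s)

    if engine == "diffusion":
        ma, ms = np.meshgrid(mu_a_grid, mu_s_grid, indexing="ij")
        r_dc = diffusion_rd(ma, ms, fx=fx_pair[0], n_tissue=ctx.n_tissue)
        r_ac = diffusion_rd(ma, ms, fx=fx_pair[1], n_tissue=ctx.n_tissue)
    else:
        r_dc = np.empty((n_a, n_s))
        r_ac = np.empty((n_a, n_s))
        for i, mu_a in enumerate(mu_a_grid):
            for j, mu_s in enumerate(mu_s_grid):
                node_seed = (int(seed) + 7919 * (i * n_s + j)) % (2**31)
                prof = mc_rd(OpticalProperties(mu_a, mu_s), ctx,
                             n_photons=n_photons, seed=node_seed)
                r_dc[i, j] = hankel_rd(prof, fx_pair[0]).value
                r_ac[i, j] = hankel_rd(prof, fx_pair[1]).value

    lut = ReflectanceLUT(
        mu_a_grid=mu_a_grid,
        mu_s_prime_grid=mu_s_grid,
        fx_pair=(float(fx_pair[0]), float(fx_pair[1])),
        r_dc=r_dc,
        r_ac=r_ac,
        n_tissue=ctx.n_tissue,
        engine=engine,
        seed=int(seed) if engine == "monte-carlo" else None,
        meta={"n_photons": n_photons} if engine == "monte-carlo" else {},
    )
    lut.validate(ratio_tol=1e-3 if engine == "diffusion" else 2e-2)
    return lut
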