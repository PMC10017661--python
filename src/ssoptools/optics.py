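"""Forward models of spatial-frequency-domain diffuse reflectance.

The workhorse is the diffusion-approximation closed form for the diffuse
reflectance of a semi-infinite homogeneous medium under sinusoidal
irradiance at spatial frequency ``fx`` — the standard SFDI forward model.
A photon-packet Monte-Carlo oracle for the same geometry lives in
:mod:`ssoptools.mc`; lookup-table construction in :mod:`ssoptools.lut`.

Units: absorption ``mu_a`` and reduced scattering ``mu_s_prime`` in mm^-1,
spatial frequency in mm^-1, reflectance dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalProperties",
    "SpatialFrequency",
    "MediumContext",
    "effective_reflection_coefficient",
    "diffusion_rd",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced-scattering coefficients of a homogeneous
    medium at a single wavelength, both in mm^-1."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_a) and self.mu_a > 0):
            raise ValueError(f"mu_a must be finite and > 0, got {self.mu_a}")
        if not (np.isfinite(self.mu_s_prime) and self.mu_s_prime > 0):
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )


@dataclass(frozen=True)
class SpatialFrequency:
    """Spatial frequency of the projected sinusoid, mm^-1."""

    fx: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fx) and self.fx >= 0):
            raise ValueError(f"fx must be finite and >= 0, got {self.fx}")


@dataclass(frozen=True)
class MediumContext:
    """Optical context of the medium: refractive index (air outside).

    The conventional soft-tissue value n = 1.4 is the default.
    """

    n_tissue: float = 1.4

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n_tissue) and self.n_tissue >= 1.0):
            raise ValueError(f"n_tissue must be >= 1, got {self.n_tissue}")


def effective_reflection_coefficient(n: float) -> float:
    """Empirical effective internal reflection coefficient R_eff(n).

    Groenhuis-style polynomial fit used by the standard SFDI diffusion
    boundary condition; for n = 1.4 it evaluates to about 0.529.
    """
    n = float(n)
    if n < 1.0:
        raise ValueError("refractive index must be >= 1")
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffusion_rd(mu_a, mu_s_prime=None, fx=0.0, n_tissue: float = 1.4):
    """Diffuse reflectance R_d(fx) of a semi-infinite homogeneous medium.

    Diffusion-approximation closed form with the partial-current boundary
    condition:

        mu_tr   = mu_a + mu_s'
        a'      = mu_s' / mu_tr
        mu_eff  = sqrt(3 mu_a mu_tr)
        mu_eff' = sqrt(mu_eff^2 + (2 pi fx)^2)
        A       = (1 - R_eff) / (2 (1 + R_eff))
        R_d     = 3 A a' / [(mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A)]

    Parameters
    ----------
    mu_a, mu_s_prime : float or array_like
        Absorption and reduced scattering, mm^-1; broadcast together.
        An :class:`OpticalProperties` may be passed as the first argument
        with ``mu_s_prime`` omitted (``None``).
    fx : float or array_like
        Spatial frequency, mm^-1 (or a :class:`SpatialFrequency`).
    n_tissue : float
        Tissue refractive index (or a :class:`MediumContext`).

    Returns
    -------
    float or ndarray
        R_d in (0, 1]; strictly decreasing in ``mu_a`` and in ``fx``.
    """
    if isinstance(mu_a, OpticalProperties):
        if mu_s_prime is not None:
            raise TypeError(
                "pass fx/n_tissue by keyword when the first argument is "
                "an OpticalProperties"
            )
        mu_a, mu_s_prime = mu_a.mu_a, mu_a.mu_s_prime
    elif mu_s_prime is None:
        raise TypeError("mu_s_prime is required when mu_a is a scalar/array")
    if isinstance(fx, SpatialFrequency):
        fx = fx.fx
    if isinstance(n_tissue, MediumContext):
        n_tissue = n_tissue.n_tissue

    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if not np.all(np.isfinite(mu_a)) or np.any(mu_a <= 0):
        raise ValueError("mu_a must be finite and > 0")
    if not np.all(np.isfinite(mu_s_prime)) or np.any(mu_s_prime <= 0):
        raise ValueError("mu_s_prime must be finite and > 0")
    if not np.all(np.isfinite(fx)) or np.any(fx < 0):
        raise ValueError("fx must be finite and >= 0")

    mu_tr = mu_a + mu_s_prime
    a_prime = mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr)
    mu_eff_p = np.sqrt(mu_eff**2 + (2.0 * np.pi * fx) ** 2)
    r_eff = effective_reflection_coefficient(n_tissue)
    big_a = (1.0 - r_eff) / (2.0 * (1.0 + r_eff))
    ratio = mu_eff_p / mu_tr
    rd = 3.0 * big_a * a_prime / ((ratio + 1.0) * (ratio + 3.0 * big_a))
    if rd.ndim == 0:
        return float(rd)
    return rd
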