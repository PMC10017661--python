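"""Two-wavelength haemoglobin unmixing and StO2 mapping.

Tissue oxygen saturation is the fraction of oxygenated haemoglobin over
total haemoglobin, StO2 = c_HbO2 / (c_HbO2 + c_Hb).  With absorption maps
at two wavelengths (red ~665 nm, NIR ~860 nm — one on each side of the
oxy/deoxy crossover) the per-pixel concentrations follow from a 2x2
Beer–Lambert system:

    mu_a(lambda_i) - mu_a,background
        = ln(10) * [eps_HbO2(lambda_i) c_HbO2 + eps_Hb(lambda_i) c_Hb]

All unit conversion (extinction in cm^-1/M, concentration in uM, mu_a in
mm^-1) happens in exactly one place, :func:`hemoglobin_mu_a` /
:data:`EPS_TO_MM`, to keep unit bugs out of the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "StO2Map",
    "hemoglobin_mu_a",
    "unmix_sto2",
    "roi_summary",
]

LN10 = np.log(10.0)
#: converts eps[cm^-1/M] * c[uM] to mu_a contribution in mm^-1 (x ln10)
EPS_TO_MM = 1e-6 * 0.1
#: default non-haemoglobin background absorption, mm^-1 (matches the
#: scene simulator's background offset so the pair is mutually inverse)
DEFAULT_BACKGROUND_MU_A = 0.001


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and Hb vs wavelength.

    Values in cm^-1 (mol/L)^-1.  The packaged default table is a
    compilation after Prahl's haemoglobin tabulation; the red wavelength
    must be Hb-dominated and the NIR wavelength HbO2-dominated, which is
    what makes the 2x2 unmixing well conditioned.
    """

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    source: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        for arr in (self.wavelengths_nm, self.eps_hbo2, self.eps_hb):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("extinction table values must be > 0")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Load the packaged haemoglobin extinction compilation."""
        ref = resources.files("ssoptools") / "data" / "hb_extinction.csv"
        with ref.open("r") as fh:
            df = pd.read_csv(fh, comment="#")
        return cls(
            wavelengths_nm=df["wavelength_nm"].to_numpy(float),
            eps_hbo2=df["eps_hbo2"].to_numpy(float),
            eps_hb=df["eps_hb"].to_numpy(float),
            source="compiled after S. Prahl's haemoglobin tabulation (OMLC)",
            version="1",
        )

    def epsilon(self, wavelength_nm: float) -> tuple[float, float]:
        """(eps_HbO2, eps_Hb) at a tabulated wavelength.

        Raises KeyError for wavelengths not in the table (no silent
        interpolation: the instrument works at discrete laser lines).
        """
        idx = np.nonzero(
            np.isclose(self.wavelengths_nm, float(wavelength_nm)))[0]
        if len(idx) == 0:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not in extinction table "
                f"(have {self.wavelengths_nm.tolist()})")
        i = int(idx[0])
        return float(self.eps_hbo2[i]), float(self.eps_hb[i])


@dataclass
class StO2Map:
    """Per-pixel oxygen saturation with quality accounting.

    ``sto2`` is stored un-clamped (a nonphysical pixel keeps its value and
    is excluded via ``quality_mask``); ``display_sto2`` returns a clamped
    copy for rendering only.  ``quality_mask`` is True where the pixel is
    trustworthy.
    """

    sto2: np.ndarray
    thb: np.ndarray  # uM
    quality_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def display_sto2(self) -> np.ndarray:
        return np.clip(self.sto2, 0.0, 1.0)


def hemoglobin_mu_a(
    sto2,
    thb_uM,
    wavelength_nm: float,
    table: ExtinctionTable | None = None,
    background_mu_a: float = DEFAULT_BACKGROUND_MU_A,
):
    """Absorption coefficient (mm^-1) of a haemoglobin mixture.

    mu_a = ln(10) [eps_HbO2 StO2 + eps_Hb (1 - StO2)] tHb + background.
    The single place where extinction units meet mu_a units.
    """
    if table is None:
        table = ExtinctionTable.default()
    e_o, e_d = table.epsilon(wavelength_nm)
    sto2 = np.asarray(sto2, dtype=float)
    thb_uM = np.asarray(thb_uM, dtype=float)
    eps_mix = e_o * sto2 + e_d * (1.0 - sto2)
    mu_a = LN10 * eps_mix * thb_uM * EPS_TO_MM + background_mu_a
    return float(mu_a) if mu_a.ndim == 0 else mu_a


def unmix_sto2(
    mu_a_665,
    mu_a_860,
    table: ExtinctionTable | None = None,
    background_mu_a: float = DEFAULT_BACKGROUND_MU_A,
    *,
    wavelengths: tuple[float, float] = (665.0, 860.0),
) -> StO2Map:
    """Solve the per-pixel 2x2 Beer–Lambert system for StO2 and tHb.

    Parameters
    ----------
    mu_a_665, mu_a_860 : array_like
        Co-registered absorption maps, mm^-1, at the two wavelengths
        (default 665/860 nm laser lines).
    table : ExtinctionTable, optional
        Extinction compilation; the packaged default when omitted.
    background_mu_a : float
        Non-haemoglobin absorption subtracted before unmixing.

    Returns
    -------
    StO2Map
        Unclamped StO2 and tHb (uM); ``quality_mask`` is False where any
        concentration is negative or tHb is non-positive.
    """
    if table is None:
        table = ExtinctionTable.default()
    mu_a_665 = np.asarray(mu_a_665, dtype=float)
    mu_a_860 = np.asarray(mu_a_860, dtype=float)
    if mu_a_665.shape != mu_a_860.shape:
        raise ValueError("absorption maps must share a shape")
    e_o1, e_d1 = table.epsilon(wavelengths[0])
    e_o2, e_d2 = table.epsilon(wavelengths[1])
    det = e_o1 * e_d2 - e_d1 * e_o2
    if abs(det) < 1e-12 * max(abs(e_o1 * e_d2), abs(e_d1 * e_o2)):
        raise ValueError("extinction matrix is singular")
    b1 = (mu_a_665 - background_mu_a) / (LN10 * EPS_TO_MM)  # eps * uM
    b2 = (mu_a_860 - background_mu_a) / (LN10 * EPS_TO_MM)
    c_o = (e_d2 * b1 - e_d1 * b2) / det
    c_d = (-e_o2 * b1 + e_o1 * b2) / det
    thb = c_o + c_d
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(thb != 0, c_o / thb, np.nan)
    quality = (c_o >= 0) & (c_d >= 0) & (thb > 0) & np.isfinite(sto2)
    return StO2Map(
        sto2=sto2,
        thb=thb,
        quality_mask=quality,
        meta={
            "wavelengths_nm": wavelengths,
            "background_mu_a": background_mu_a,
            "extinction_version": table.version,
        },
    )


def roi_summary(sto2_map: StO2Map, roi_masks: np.ndarray) -> pd.DataFrame:
    """Per-ROI mean +/- SD of StO2 over quality-valid pixels.

    Parameters
    ----------
    sto2_map : StO2Map
    roi_masks : ndarray of int
        Labelled mask (0 = background, 1..k = ROIs), same shape as the map.

    Returns
    -------
    DataFrame with columns roi, n_pixels, n_valid, sto2_mean, sto2_sd,
    thb_mean, flagged — flagged is True when a ROI has no valid pixel
    (its means are NaN; the row is kept, never dropped).
    """
    roi_masks = np.asarray(roi_masks)
    if roi_masks.shape != sto2_map.sto2.shape:
        raise ValueError("ROI masks must match the map shape")
    rows = []
    for label in sorted(int(v) for v in np.unique(roi_masks) if v != 0):
        sel = roi_masks == label
        valid = sel & sto2_map.quality_mask
        n_valid = int(valid.sum())
        if n_valid:
            vals = sto2_map.sto2[valid]
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n_valid > 1 else 0.0
            thb_mean = float(np.mean(sto2_map.thb[valid]))
        else:
            mean = sd = thb_mean = float("nan")
        rows.append({
            "roi": label,
            "n_pixels": int(sel.sum()),
            "n_valid": n_valid,
            "sto2_mean": mean,
            "sto2_sd": sd,
            "thb_mean": thb_mean,
            "flagged": n_valid == 0,
        })
    return pd.DataFrame(rows)
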