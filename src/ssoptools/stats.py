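"""Study statistics: lactate normalisation, correlation, group tests.

Mirrors the analysis shape of an ischaemia study: capillary lactates are
normalised against systemic lactates (difference by default, ratio as an
option), continuous variables are compared with a pooled-variance
two-sample t test preceded by a Kolmogorov–Smirnov normality check whose
outcome is reported (never silently acted on), and associations are
summarised with the Pearson product-moment correlation (Spearman exposed
as an option).  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "normalise_lactates",
    "pearson",
    "students_t",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str = "pearson"


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: pooled-variance Student's t with a KS
    normality check per group (standardised against a normal reference).
    ``ks_pass`` flags whether both groups look parametric at the 5% level;
    it is informational only."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ks_statistics: tuple[float, float]
    ks_p_values: tuple[float, float]
    ks_pass: bool


def normalise_lactates(
    records: pd.DataFrame,
    mode: str = "difference",
) -> pd.DataFrame:
    """Normalise capillary lactates against systemic lactates.

    ``difference`` (default): capillary - systemic, mmol/L.
    ``ratio``: capillary / systemic, dimensionless; rows with non-positive
    systemic lactate get a True ``normalisation_error`` flag and NaN.

    Returns a copy with ``normalised_lactate`` and ``normalisation_error``
    columns; the mode is recorded in ``DataFrame.attrs['normalisation']``.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    for col in ("capillary_lactate", "systemic_lactate"):
        if col not in records.columns:
            raise KeyError(f"missing column {col!r}")
    out = records.copy()
    cap = out["capillary_lactate"].to_numpy(float)
    sys_ = out["systemic_lactate"].to_numpy(float)
    if np.any(cap <= 0):
        raise ValueError("capillary lactates must be positive")
    if mode == "difference":
        out["normalised_lactate"] = cap - sys_
        out["normalisation_error"] = False
    else:
        bad = sys_ <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(bad, np.nan, cap / np.where(bad, 1.0, sys_))
        out["normalised_lactate"] = ratio
        out["normalisation_error"] = bad
    out.attrs["normalisation"] = mode
    return out


def pearson(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation between two vectors with a two-sided p value.

    Product-moment by default; ``method="spearman"`` ranks first.
    Requires equal lengths >= 3, finite values and nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(res.statistic), n=len(x),
                             p_value=float(res.pvalue), method=method)


def students_t(a, b, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Pooled-variance two-sample Student's t test.

    Each group is first standardised and checked against a standard
    normal with a one-sample KS test; the outcome is reported in the
    result, not acted on.  Raises on zero pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    if sd_a == 0 and sd_b == 0:
        raise ValueError("zero pooled variance: t undefined")

    def _ks(v, sd):
        if sd == 0:
            return float("nan"), float("nan")
        z = (v - np.mean(v)) / sd
        res = sps.kstest(z, "norm")
        return float(res.statistic), float(res.pvalue)

    ks_a = _ks(a, sd_a)
    ks_b = _ks(b, sd_b)
    t_res = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    ks_pass = bool(
        np.nan_to_num(ks_a[1], nan=1.0) > 0.05
        and np.nan_to_num(ks_b[1], nan=1.0) > 0.05)
    return GroupComparison(
        labels=tuple(labels),
        means=(float(np.mean(a)), float(np.mean(b))),
        sds=(sd_a, sd_b),
        t_statistic=float(t_res.statistic),
        degrees_of_freedom=df,
        p_value=float(t_res.pvalue),
        ks_statistics=(ks_a[0], ks_b[0]),
        ks_p_values=(ks_a[1], ks_b[1]),
        ks_pass=ks_pass,
    )
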