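"""Study statistics against hand-computed textbook oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssoptools import normalise_lactates, pearson, simulate_study, students_t


def _records(cap, sys_):
    return pd.DataFrame({"capillary_lactate": cap, "systemic_lactate": sys_})


def test_normalise_difference_and_ratio():
    df = _records([5.8, 2.0], [1.0, 2.0])
    diff = normalise_lactates(df, "difference")
    assert list(diff["normalised_lactate"]) == [4.8, 0.0]
    assert diff.attrs["normalisation"] == "difference"
    ratio = normalise_lactates(df, "ratio")
    assert list(ratio["normalised_lactate"]) == [5.8, 1.0]


def test_normalise_ratio_flags_nonpositive_systemic():
    df = _records([2.0, 3.0], [0.0, 1.5])
    out = normalise_lactates(df, "ratio")
    assert bool(out["normalisation_error"].iloc[0])
    assert np.isnan(out["normalised_lactate"].iloc[0])
    assert not bool(out["normalisation_error"].iloc[1])


def test_normalise_rejects_bad_inputs():
    with pytest.raises(ValueError):
        normalise_lactates(_records([-1.0], [1.0]))
    with pytest.raises(KeyError):
        normalise_lactates(pd.DataFrame({"capillary_lactate": [1.0]}))
    with pytest.raises(ValueError):
        normalise_lactates(_records([1.0], [1.0]), mode="zscore")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def test_pearson_textbook_oracle():
    """x=(1,2,3,4), y=(2,1,4,3): covariance 3/3, sx*sy = 5/3 by hand,
    so r = 3/5 = 0.6; p = 0.4 from the t transform with 2 df."""
    res = pearson([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.r == pytest.approx(0.6, abs=1e-12)
    assert res.n == 4
    assert res.p_value == pytest.approx(0.4, abs=1e-10)


def test_pearson_perfect_linear():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson(x, -x).r == pytest.approx(-1.0)


def test_pearson_symmetry_and_affine_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
    assert pearson(3 * x + 2, y).r == pytest.approx(pearson(x, y).r,
                                                    abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=4, max_size=20, unique=True))
def test_pearson_bounds_property(x):
    rng = np.random.default_rng(len(x))
    y = rng.normal(size=len(x))
    r = pearson(np.asarray(x), y).r
    assert -1.0 <= r <= 1.0


def test_pearson_input_validation():
    with pytest.raises(ValueError):
        pearson([1, 2], [3, 4])
    with pytest.raises(ValueError):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson([1, 2, np.nan], [1, 2, 3])


def test_spearman_option():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [1.0, 8.0, 27.0, 64.0]  # monotone, nonlinear
    assert pearson(x, y, method="spearman").r == pytest.approx(1.0)
    assert pearson(x, y).r < 1.0


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------


def test_students_t_textbook_oracle():
    """a=(1,2,3), b=(2,4,6): pooled s^2 = (2+8)/4 = 2.5, so
    t = -2 / sqrt(2.5 * 2/3) = -1.549193..., df = 4, p = 0.19626."""
    res = students_t([1, 2, 3], [2, 4, 6])
    assert res.t_statistic == pytest.approx(-1.5491933384829668, rel=1e-12)
    assert res.degrees_of_freedom == 4
    assert res.p_value == pytest.approx(0.19626117814926966, rel=1e-9)
    assert res.means == (2.0, 4.0)


def test_students_t_identical_samples():
    res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_students_t_zero_variance_error():
    with pytest.raises(ValueError):
        students_t([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


def test_students_t_reports_ks_check():
    rng = np.random.default_rng(1)
    res = students_t(rng.normal(size=50), rng.normal(1.0, 1.0, size=50))
    assert len(res.ks_statistics) == 2
    assert all(0 <= p <= 1 for p in res.ks_p_values)
    assert res.ks_pass  # normal draws should look parametric


def test_type_one_error_rate_near_nominal():
    """Same-distribution replicates reject at ~5% under alpha = 0.05."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        if students_t(a, b).p_value < 0.05:
            rejections += 1
    assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# integration with the study generator
# ---------------------------------------------------------------------------


def test_synthetic_study_negative_lactate_sto2_association():
    df = normalise_lactates(simulate_study(seed=7))
    res = pearson(df["normalised_lactate"], df["sto2_measured"])
    assert res.r < 0
    assert res.p_value < 0.01


def test_noiseless_linear_study_gives_perfect_anticorrelation():
    df = simulate_study(seed=0, lactate_noise=0.0, sto2_sd=0.0,
                        systemic_sd=0.0)
    # with all noise off, lactate excess and StO2 are both linear in time
    isch = df[df["roi"] == 1]
    norm = isch["capillary_lactate"] - isch["systemic_lactate"]
    res = pearson(norm, isch["sto2_measured"])
    assert res.r == pytest.approx(-1.0, abs=1e-9)
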