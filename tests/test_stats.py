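"""Study statistics: SUV, bin width, multiplicity, paired tests, registration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcewex import (
    association_report,
    fd_bin_width,
    fwe_alpha,
    rigid_register,
    suv,
    treatment_report,
)
from dcewex import test_retest_report as retest_report
from dcewex.registration import RigidTransform, apply_rigid
from dcewex.stats import wilcoxon_rank_sum, wilcoxon_signed_rank

# --- SUV ----------------------------------------------------------------


def test_suv_values_and_linearity():
    assert suv(5000.0, 20.0, 1e6) == pytest.approx(0.1)
    # uniform whole-body distribution: activity = dose/weight -> SUV = 1
    assert suv(1e6 / 25.0, 25.0, 1e6) == pytest.approx(1.0)
    assert suv(5000.0, 40.0, 1e6) == pytest.approx(2 * suv(5000.0, 20.0, 1e6))
    with pytest.raises(ValueError):
        suv(5000.0, 0.0, 1e6)


# --- Freedman-Diaconis --------------------------------------------------


def test_fd_bin_width_closed_form():
    v = np.arange(1001, dtype=float)  # IQR = 500, N = 1001
    q1, q3 = np.quantile(v, [0.25, 0.75])
    assert fd_bin_width(v) == pytest.approx(2 * (q3 - q1) * 1001 ** (-1 / 3))
    # seeded uniform sample, N = 8000: W = 2 IQR / 20
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 8000)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    assert fd_bin_width(x) == pytest.approx(2 * (q3 - q1) / 20.0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(c=st.floats(0.1, 100.0))
def test_fd_scale_equivariance(c):
    v = np.array([1.0, 2.0, 4.0, 8.0, 9.0, 13.0])
    assert fd_bin_width(c * v) == pytest.approx(c * fd_bin_width(v), rel=1e-12)


def test_fd_zero_iqr_errors():
    with pytest.raises(ValueError, match="IQR"):
        fd_bin_width(np.ones(50))


# --- FWER ---------------------------------------------------------------


def test_fwe_alpha_93_features():
    assert fwe_alpha(1) == pytest.approx(0.05)
    # Sidak at m = 93 reproduces the 0.0006 threshold to 4 decimals
    assert round(fwe_alpha(93), 4) == 0.0006
    assert fwe_alpha(93, method="bonferroni") == pytest.approx(0.05 / 93)
    with pytest.raises(ValueError):
        fwe_alpha(93, fwer=1.5)


# --- exact small-sample tests vs enumeration oracles -------------------


def test_rank_sum_matches_enumeration():
    a = [1.3, 0.8, 2.1, 1.7, 0.2]
    b = [2.5, 3.0, 1.1, 2.8, 3.3]
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    w_obs = ranks[:5].sum()
    ws = np.array([sum(c) for c in itertools.combinations(ranks, 5)])
    expected = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
    assert wilcoxon_rank_sum(a, b) == pytest.approx(expected, rel=1e-12)
    # extreme split: p = 2 / C(10,5)
    assert wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == \
        pytest.approx(2 / 252)


def test_signed_rank_matches_sign_flip_enumeration():
    d = np.array([0.5, -1.2, 2.0, 0.9, -0.1])
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=5):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    expected = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
    assert wilcoxon_signed_rank(d) == pytest.approx(expected, rel=1e-12)
    # five paired decreases: p = 2 / 2^5
    assert wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 6]) == \
        pytest.approx(0.0625)
    # all-zero differences: p = 1 by convention
    assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0


# --- test-retest report -------------------------------------------------


def test_retest_identical_scans():
    rng = np.random.default_rng(2)
    m = rng.random((5, 5, 5))
    mask = np.ones((5, 5, 5), dtype=bool)
    rep = retest_report({"Fp": m}, {"Fp": m.copy()}, mask)
    assert rep.loc["Fp", "pearson_r"] == pytest.approx(1.0)
    assert rep.loc["Fp", "median_pct_change"] == 0.0
    assert rep.loc["Fp", "signed_rank_p"] == 1.0


def test_retest_constant_shift():
    rng = np.random.default_rng(3)
    m = rng.random(100).reshape(10, 10)
    mask = np.ones((10, 10), dtype=bool)
    rep = retest_report({"v": m}, {"v": m + 0.5}, mask)
    assert rep.loc["v", "pearson_r"] == pytest.approx(1.0)
    assert rep.loc["v", "signed_rank_p"] < 1e-6


def test_retest_shape_mismatch_errors():
    with pytest.raises(ValueError):
        retest_report({"a": np.ones((2, 2))}, {"a": np.ones((3, 3))},
                           np.ones((2, 2), dtype=bool))


# --- association --------------------------------------------------------


def test_association_perfect_and_null():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    rep = association_report(pd.DataFrame({"kio": x}), 2.0 * x + 1.0)
    assert rep.loc["kio", "r_squared"] == pytest.approx(1.0)
    assert rep.loc["kio", "slope"] == pytest.approx(2.0)
    rng = np.random.default_rng(4)
    rep0 = association_report(pd.DataFrame({"kio": rng.random(500)}),
                              rng.random(500))
    assert rep0.loc["kio", "r_squared"] < 0.02
    repc = association_report(pd.DataFrame({"kio": np.ones(7)}), x)
    assert repc.loc["kio", "constant_predictor"]


# --- treatment report ---------------------------------------------------


def _cohort(effect_tx2=0.35):
    rows = []
    rng = np.random.default_rng(9)
    for g, mult in (("control", (1, 1, 1)), ("treated", (1, 0.5, effect_tx2))):
        for i in range(5):
            base = 2.0 + 0.2 * rng.standard_normal()
            for j, tp in enumerate(("Pre-Tx", "Tx-1", "Tx-2")):
                rows.append({"animal": f"{g}{i}", "group": g, "timepoint": tp,
                             "kio": base * mult[j] * (1 + 0.05 * rng.standard_normal())})
    return pd.DataFrame(rows)


def test_treatment_normalization_and_tests():
    df = _cohort()
    norm, tests, excluded = treatment_report(df)
    assert excluded == []
    pre = norm[norm["timepoint"] == "Pre-Tx"]["kio"]
    assert np.allclose(pre, 1.0)
    # strong separation at Tx-2 -> the exact rank-sum floor p = 2/252
    assert tests.loc[("Tx-2", "kio"), "rank_sum_p"] == pytest.approx(2 / 252)
    # treated group decreased in all five animals -> signed-rank p = 0.0625
    assert tests.loc[("Tx-2", "kio"), "signed_rank_p_treated"] == \
        pytest.approx(0.0625)


def test_treatment_missing_timepoint_excluded():
    df = _cohort()
    df = df[~((df["animal"] == "treated0") & (df["timepoint"] == "Tx-2"))]
    norm, tests, excluded = treatment_report(df)
    assert excluded == ["treated0"]


# --- rigid registration -------------------------------------------------


@pytest.fixture(scope="module")
def smooth_volume():
    from scipy import ndimage

    rng = np.random.default_rng(0)
    v = ndimage.gaussian_filter(rng.random((48, 48, 48)), 4.0)
    return (v - v.min()) / (v.max() - v.min())


def test_register_identity(smooth_volume):
    tr, res, info = rigid_register(smooth_volume, smooth_volume)
    assert np.abs(tr.translation).max() < 0.01
    assert np.abs(tr.angles_deg).max() < 0.01
    assert info["final_mse"] <= info["initial_mse"]


def test_register_recovers_translation(smooth_volume):
    moved = apply_rigid(smooth_volume, RigidTransform((0, 0, 0), (3.0, -2.0, 1.0)))
    tr, res, info = rigid_register(moved, smooth_volume)
    # registering the moved volume back recovers the inverse transform
    assert np.abs(np.array(tr.translation) + np.array([3.0, -2.0, 1.0])).max() < 0.1
    assert info["final_mse"] < info["initial_mse"]


def test_register_recovers_rotation(smooth_volume):
    moved = apply_rigid(smooth_volume, RigidTransform((5.0, 0, 0), (0, 0, 0)))
    tr, res, info = rigid_register(moved, smooth_volume)
    assert abs(tr.angles_deg[0] + 5.0) < 0.2
    assert np.abs(tr.translation).max() < 0.2
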