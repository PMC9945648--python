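"""Study-level statistics: test–retest, PET association, treatment response.

Also the two protocol-arithmetic rules used for map discretization and
multiplicity control (Freedman–Diaconis bin width, family-wise error
rate), the standardized uptake value, and rigid registration of the
retest scan onto the test scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registration import rigid_register  # re-exported

__all__ = [
    "suv",
    "fd_bin_width",
    "fwe_alpha",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "test_retest_report",
    "association_report",
    "treatment_report",
    "rigid_register",
]


def suv(activity_bq_per_ml, weight_g, dose_bq):
    """Body-weight standardized uptake value.

    SUV = activity (Bq/mL) * body weight (g) / injected dose (Bq),
    dimensionless assuming 1 g/mL tissue density.  A uniformly
    distributed tracer (activity = dose/weight) gives SUV = 1.
    """
    activity = np.asarray(activity_bq_per_ml, dtype=float)
    if np.any(np.asarray(weight_g) <= 0) or np.any(np.asarray(dose_bq) <= 0):
        raise ValueError("weight and dose must be positive")
    if np.any(activity < 0):
        raise ValueError("activity must be nonnegative")
    out = activity * weight_g / dose_bq
    return float(out) if out.ndim == 0 else out


def fd_bin_width(values) -> float:
    """Freedman–Diaconis histogram bin width W = 2 IQR N^(-1/3).

    IQR uses linear-interpolation quantiles.  A zero IQR (more than
    half the sample tied) is an error — fall back to a range-based or
    fixed width in that case.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError(
            "IQR is zero; the Freedman–Diaconis width degenerates — "
            "use a range-based or fixed bin width instead"
        )
    return float(2.0 * iqr * v.size ** (-1.0 / 3.0))


def fwe_alpha(m: int, fwer: float = 0.05, method: str = "sidak") -> float:
    """Per-test significance level controlling the family-wise error rate.

    Šidák: alpha = 1 - (1 - FWER)^(1/m); Bonferroni: FWER/m.  For the
    93 texture features at FWER 0.05, Šidák gives 0.0006 to four
    decimals (Bonferroni rounds to 0.0005).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < fwer < 1:
        raise ValueError("fwer must be in (0, 1)")
    if method == "sidak":
        return float(1.0 - (1.0 - fwer) ** (1.0 / m))
    if method == "bonferroni":
        return float(fwer / m)
    raise ValueError(f"unknown method {method!r}")


_EXACT_SIGNED_N_MAX = 20   # 2^n sign assignments enumerated
_EXACT_RANKSUM_N_MAX = 16  # C(n1+n2, n1) arrangements enumerated


def wilcoxon_signed_rank(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention).  For n <= 20
    nonzero pairs the p-value is exact by full enumeration of the 2^n
    sign assignments on the observed midranks (ties permitted); above
    that, the normal approximation with continuity correction.  All
    differences zero returns p = 1 by convention.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n <= _EXACT_SIGNED_N_MAX:
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # distribution of W+ over all sign assignments, by convolution
        # over ranks: each rank contributes 0 or its value
        scale = 2  # midranks are multiples of 1/2
        vals = np.round(ranks * scale).astype(int)
        total = vals.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for v in vals:
            dist[v:] = dist[v:] + dist[:-v or None]
        dist /= dist.sum()
        w = int(round(w_obs * scale))
        p_low = dist[: w + 1].sum()
        p_high = dist[w:].sum()
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       method="approx", alternative="two-sided")
    return float(res.pvalue)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact by full enumeration of the C(n1+n2, n1) group assignments of
    the pooled midranks when n1 + n2 <= 16 (ties permitted), otherwise
    the normal approximation with continuity correction.
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    if n1 + n2 <= _EXACT_RANKSUM_N_MAX:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        ws = np.array([sum(c) for c in combinations(ranks, n1)])
        eps = 1e-9
        p_low = np.mean(ws <= w_obs + eps)
        p_high = np.mean(ws >= w_obs - eps)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


def test_retest_report(maps1: dict, maps2: dict, mask: np.ndarray) -> pd.DataFrame:
    """Voxel-paired repeatability statistics per parameter.

    ``maps1``/``maps2`` map parameter name -> registered, same-shape 3D
    arrays (or flat arrays); ``mask`` selects the tumor voxels.  For
    each parameter: Pearson r across paired voxels, Wilcoxon
    signed-rank p, and the median percent change
    100 (median_2 - median_1)/median_1.
    """
    if set(maps1) != set(maps2):
        raise ValueError("the two scans report different parameters")
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for name in maps1:
        a = np.asarray(maps1[name], dtype=float)
        b = np.asarray(maps2[name], dtype=float)
        if a.shape != b.shape or a.shape != mask.shape:
            raise ValueError(f"shape mismatch for {name}")
        x, y = a[mask], b[mask]
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if np.std(x) == 0 or np.std(y) == 0:
            r = 1.0 if np.array_equal(x, y) else np.nan
        else:
            r = float(sps.pearsonr(x, y).statistic)
        p = wilcoxon_signed_rank(y, x)
        m1, m2 = np.median(x), np.median(y)
        pct = 100.0 * (m2 - m1) / m1 if m1 != 0 else np.nan
        rows.append({"parameter": name, "pearson_r": r,
                     "signed_rank_p": p, "median_pct_change": pct, "n_voxels": x.size})
    return pd.DataFrame(rows).set_index("parameter")


def association_report(roi_medians: pd.DataFrame, suv_means) -> pd.DataFrame:
    """Per-parameter ordinary least squares of SUV on the tumor medians.

    ``roi_medians`` has one row per tumor and one column per parameter;
    ``suv_means`` is the per-tumor mean SUV.  Returns slope, intercept
    and R^2 per parameter.  Constant predictors are flagged (NaN R^2).
    """
    y = np.asarray(suv_means, dtype=float)
    if len(roi_medians) < 3 or y.size < 3:
        raise ValueError("need at least 3 tumors")
    if len(roi_medians) != y.size:
        raise ValueError("medians and SUV must cover the same tumors")
    rows = []
    for name in roi_medians.columns:
        x = roi_medians[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"parameter": name, "slope": np.nan, "intercept": np.nan,
                         "r_squared": np.nan, "constant_predictor": True})
            continue
        res = sps.linregress(x, y)
        rows.append({"parameter": name, "slope": float(res.slope),
                     "intercept": float(res.intercept),
                     "r_squared": float(res.rvalue ** 2),
                     "constant_predictor": False})
    return pd.DataFrame(rows).set_index("parameter")


def treatment_report(cohort: pd.DataFrame, baseline: str = "Pre-Tx"):
    """Baseline-normalized trajectories with group and paired tests.

    ``cohort`` is long-form with columns ``animal``, ``group``
    (control/treated), ``timepoint`` and one column per parameter.
    Each animal's values are divided by its baseline value; animals
    missing any time point are excluded (reported).  At each
    post-baseline time point the groups are compared by the exact
    Wilcoxon rank-sum test on normalized values, and each group's
    change from baseline by the exact signed-rank test on the paired
    raw values.

    Returns ``(normalized, tests, excluded_animals)``.
    """
    required = {"animal", "group", "timepoint"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort must have columns {sorted(required)}")
    params = [c for c in cohort.columns if c not in required]
    timepoints = list(dict.fromkeys(cohort["timepoint"]))
    if baseline not in timepoints:
        raise ValueError(f"baseline {baseline!r} not among time points {timepoints}")

    counts = cohort.groupby("animal")["timepoint"].nunique()
    complete = counts[counts == len(timepoints)].index
    excluded = sorted(set(cohort["animal"]) - set(complete))
    df = cohort[cohort["animal"].isin(complete)].copy()

    base = df[df["timepoint"] == baseline].set_index("animal")[params]
    norm = df.copy()
    for p in params:
        norm[p] = df.apply(lambda r: r[p] / base.loc[r["animal"], p], axis=1)

    rows = []
    for tp in timepoints:
        sub = norm[norm["timepoint"] == tp]
        raw = df[df["timepoint"] == tp].set_index("animal")
        for p in params:
            g1 = sub[sub["group"] == "control"][p].to_numpy()
            g2 = sub[sub["group"] == "treated"][p].to_numpy()
            p_group = (wilcoxon_rank_sum(g1, g2)
                       if g1.size and g2.size and tp != baseline else np.nan)
            row = {"timepoint": tp, "parameter": p, "rank_sum_p": p_group}
            for gname in ("control", "treated"):
                animals = df[(df["group"] == gname)]["animal"].unique()
                if tp == baseline or len(animals) == 0:
                    row[f"signed_rank_p_{gname}"] = np.nan
                    continue
                now = raw.loc[raw["group"] == gname, p]
                then = base.loc[now.index, p]
                row[f"signed_rank_p_{gname}"] = wilcoxon_signed_rank(
                    now.to_numpy(), then.to_numpy())
            rows.append(row)
    tests = pd.DataFrame(rows).set_index(["timepoint", "parameter"])
    return norm, tests, excluded
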