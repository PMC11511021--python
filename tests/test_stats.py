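"""Replicate statistics, rank tests, and the permutational factorial ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from turfcam.stats import (
    PermutationAnova,
    aggregate_replicates,
    dunn_control,
    kruskal_wallis,
    pearson,
    perm_anova,
    replicate_cv,
    sensitivity_report,
    significance_symbol,
)


# ---------------------------------------------------------------------------
# aggregation / CV / correlation
# ---------------------------------------------------------------------------


def _rep_frame(values, metric="m"):
    return pd.DataFrame(
        {
            "sample_id": ["s"] * len(values),
            "variant": ["JPG"] * len(values),
            metric: values,
        }
    )


def test_aggregate_replicates_excludes_undefined():
    df = _rep_frame([0.2, np.nan, 0.4])
    out = aggregate_replicates(df, ["m"])
    assert out.loc[0, "m"] == pytest.approx(0.3)
    assert out.loc[0, "n_m"] == 2


def test_aggregate_all_undefined_stays_undefined():
    out = aggregate_replicates(_rep_frame([np.nan, np.nan]), ["m"])
    assert math.isnan(out.loc[0, "m"])
    assert out.loc[0, "n_m"] == 0


@pytest.mark.parametrize(
    "values, expected",
    [
        ([10, 10, 10], 0.0),
        ([1, 2, 3], 0.5),  # sd 1 / mean 2
        ([-3.5, -3.6, -3.7], -0.1 / 3.6),  # sign follows the mean
    ],
)
def test_replicate_cv_examples(values, expected):
    out = replicate_cv(_rep_frame(values), ["m"])
    assert out.loc[0, "m"] == pytest.approx(expected, abs=1e-6)


def test_replicate_cv_undefined_cases():
    assert math.isnan(replicate_cv(_rep_frame([5.0]), ["m"]).loc[0, "m"])  # single replicate
    assert math.isnan(replicate_cv(_rep_frame([-1.0, 1.0]), ["m"]).loc[0, "m"])  # zero mean


def test_pearson_examples():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1) == pytest.approx((1.0, 1.0))
    assert pearson(x, -x)[0] == pytest.approx(-1.0)
    r, r2 = pearson([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)
    assert r2 == pytest.approx(0.64)


def test_pearson_pairwise_deletion_and_degenerate():
    r, _ = pearson([1, 2, np.nan, 4], [2, 4, 100, 8])
    assert r == pytest.approx(1.0)
    assert math.isnan(pearson([1, 1, 1], [1, 2, 3])[0])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def test_kruskal_wallis_hand_computed():
    H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert H == pytest.approx(3.857, abs=1e-3)
    assert p == pytest.approx(1 - sps.chi2.cdf(H, df=1))


def test_kruskal_wallis_identical_observations():
    H, p = kruskal_wallis([[2, 2], [2, 2, 2]])
    assert H == 0.0 and p == 1.0


def test_kruskal_wallis_matches_anova_on_ranks(rng):
    """Tie-corrected H equals the rank-transform one-way ANOVA identity."""
    groups = [rng.normal(size=7), rng.normal(size=9), rng.normal(size=5)]
    H, _ = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    # H = (n-1) * SS_between / SS_total on ranks
    idx = np.cumsum([0] + [len(g) for g in groups])
    ss_total = np.sum((ranks - ranks.mean()) ** 2)
    ss_between = sum(
        len(g) * (ranks[i0:i1].mean() - ranks.mean()) ** 2
        for g, i0, i1 in zip(groups, idx[:-1], idx[1:])
    )
    assert H == pytest.approx((n - 1) * ss_between / ss_total, abs=1e-10)


def test_dunn_identical_groups():
    out = dunn_control({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1]}, control="a")
    assert np.allclose(out["z"], 0.0)
    assert np.allclose(out["p_adjusted"], 1.0)


def test_dunn_two_groups_matches_ranksum_normal_approximation(rng):
    """With two groups Dunn's z reduces to the tie-corrected MW z."""
    x = rng.integers(0, 8, 12).astype(float)  # ties on purpose
    y = rng.integers(2, 10, 9).astype(float)
    out = dunn_control({"ctrl": x, "other": y}, control="ctrl")
    z_dunn = float(out.loc["other", "z"])

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    N = n1 + n2
    U1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    z_mw = (U1 - n1 * n2 / 2.0) / math.sqrt(var)
    assert abs(z_dunn) == pytest.approx(abs(z_mw), abs=1e-6)
    assert float(out.loc["other", "p"]) == pytest.approx(2 * sps.norm.sf(abs(z_mw)), abs=1e-6)


def test_dunn_bonferroni_factor_is_k_minus_one(rng):
    groups = {f"v{i}": rng.normal(size=6) for i in range(8)}
    out = dunn_control(groups, control="v0")
    assert len(out) == 7
    unadj = out["p"].to_numpy()
    adj = out["p_adjusted"].to_numpy()
    assert np.allclose(adj, np.minimum(1.0, unadj * 7))


def test_dunn_requires_control():
    with pytest.raises(ValueError):
        dunn_control({"a": [1], "b": [2]}, control="zzz")


# ---------------------------------------------------------------------------
# permutational factorial ANOVA
# ---------------------------------------------------------------------------


def _factorial_frame(rng, mow=(2.5, 5.0), irr=(100, 30), dates=(1, 2), reps=2, effect=0.0):
    rows = []
    for m in mow:
        for i in irr:
            for d in dates:
                for _ in range(reps):
                    y = rng.normal() + (effect if i == irr[-1] else 0.0)
                    rows.append({"mowing_height": m, "irrigation": i, "date": d, "y": y})
    return pd.DataFrame(rows)


def test_eta_squared_matches_ols_decomposition(rng):
    df = _factorial_frame(rng, reps=3, effect=1.0)
    res = perm_anova(df, "y", n_perm=200, seed=0)
    for e in res.effects.index:
        ss = res.effects.loc[e, "ss"]
        assert res.effects.loc[e, "eta_p_sq"] == pytest.approx(ss / (ss + res.ss_error), abs=1e-10)
    # F consistency with the SS decomposition
    for e in res.effects.index:
        row = res.effects.loc[e]
        assert row["F"] == pytest.approx(
            (row["ss"] / row["df"]) / (res.ss_error / res.df_error), abs=1e-10
        )


def test_permutation_p_invariant_to_level_relabeling(rng):
    df = _factorial_frame(rng, reps=3, effect=0.8)
    res1 = perm_anova(df, "y", n_perm=500, seed=7)
    relabeled = df.copy()
    relabeled["irrigation"] = relabeled["irrigation"].map({100: "full", 30: "deficit"})
    relabeled["mowing_height"] = relabeled["mowing_height"].map({2.5: "short", 5.0: "tall"})
    res2 = perm_anova(relabeled, "y", n_perm=500, seed=7)
    eff1 = res1.effects.sort_index()
    eff2 = res2.effects.rename(
        index={
            "mowing_height:irrigation": "mowing_height:irrigation",
        }
    ).sort_index()
    assert np.allclose(eff1["F"], eff2["F"])
    assert np.allclose(eff1["p_perm"], eff2["p_perm"])


def test_sampled_p_close_to_exhaustive_on_tiny_design(rng):
    df = _factorial_frame(rng, dates=(1,), reps=2, effect=1.5)  # 2x2, 8 observations
    exhaustive = perm_anova(df, "y", factors=("mowing_height", "irrigation"), exhaustive=True)
    sampled = perm_anova(df, "y", factors=("mowing_height", "irrigation"), n_perm=4000, seed=3)
    diff = (exhaustive.effects["p_perm"] - sampled.effects["p_perm"]).abs().max()
    assert diff < 0.02


def test_empty_cell_error_names_the_cell(rng):
    df = _factorial_frame(rng, reps=2)
    df = df[~((df.mowing_height == 2.5) & (df.irrigation == 30) & (df.date == 2))]
    with pytest.raises(ValueError, match="mowing_height"):
        PermutationAnova(df, "y")


def test_strong_effect_is_detected(rng):
    df = _factorial_frame(rng, mow=(2.5, 5.0, 7.5), irr=(100, 65, 30), dates=(1, 2), reps=3,
                          effect=2.0)
    res = perm_anova(df, "y", n_perm=999, seed=1)
    assert res.effects.loc["irrigation", "p_perm"] <= 0.01
    assert res.effects.loc["irrigation", "eta_p_sq"] > 0.2
    assert "irrigation" in res.summary()


def test_fit_is_reproducible_under_seed(rng):
    df = _factorial_frame(rng, reps=3, effect=0.5)
    a = perm_anova(df, "y", n_perm=300, seed=42).effects
    b = perm_anova(df, "y", n_perm=300, seed=42).effects
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# sensitivity report
# ---------------------------------------------------------------------------


def test_sensitivity_report_identical_data_has_no_flags(rng):
    base = rng.normal(size=40)
    rows = []
    for v in ("JPG", "TIF", "JPG CC"):
        for x in base:
            rows.append({"variant": v, "m": x})
    medians, flags, kw = sensitivity_report(pd.DataFrame(rows), ["m"], control="JPG")
    assert (flags.loc[["TIF", "JPG CC"], "m"] == "NS").all()
    assert kw["m"] == "NS"
    assert medians.loc["JPG", "m"] == pytest.approx(np.median(base))


def test_sensitivity_report_flags_large_shift(rng):
    base = rng.normal(size=60)
    rows = []
    for v in ("JPG", "TIF"):
        for x in base:
            rows.append({"variant": v, "m": x + (10.0 if v == "TIF" else 0.0)})
    medians, flags, kw = sensitivity_report(pd.DataFrame(rows), ["m"], control="JPG")
    assert flags.loc["TIF", "m"] == "***"
    assert kw["m"] == "***"
    assert flags.loc["JPG", "m"] == "-"


def test_significance_symbols():
    assert significance_symbol(0.2) == "NS"
    assert significance_symbol(0.04) == "*"
    assert significance_symbol(0.009) == "**"
    assert significance_symbol(0.0005) == "***"
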