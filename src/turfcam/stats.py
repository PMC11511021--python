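"""Statistical battery for correction-sensitivity analysis.

Replicate aggregation and coefficients of variation, Pearson correlation,
Kruskal-Wallis with Dunn's control-vs-others post hoc (Bonferroni), and a
permutational factorial ANOVA with partial eta-squared effect sizes.

The permutation ANOVA is exposed statsmodels-style: build a
:class:`PermutationAnova` from a tidy table, call :meth:`~PermutationAnova.fit`
and read the :class:`PermutationAnovaResults`.  Permutation p-values use
Freedman-Lane residual permutation under each effect's reduced model, with
Type III sums of squares on sum-to-zero contrasts, so the test remains valid
for mildly unbalanced designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_replicates",
    "replicate_cv",
    "pearson",
    "kruskal_wallis",
    "dunn_control",
    "PermutationAnova",
    "PermutationAnovaResults",
    "perm_anova",
    "sensitivity_report",
    "significance_symbol",
]

DEFAULT_FACTORS = ("mowing_height", "irrigation", "date")


# ---------------------------------------------------------------------------
# replicate aggregation and dispersion
# ---------------------------------------------------------------------------


def aggregate_replicates(records: pd.DataFrame, metrics, by=("sample_id", "variant")) -> pd.DataFrame:
    """Arithmetic mean per metric per sample x variant.

    Undefined (NaN) replicate values are excluded pairwise; a metric whose
    replicates are all undefined stays NaN.  Adds ``n_<metric>`` columns with
    the number of defined replicates that entered each mean.
    """
    by = list(by)
    g = records.groupby(by, sort=False)
    out = g[list(metrics)].mean()
    counts = g[list(metrics)].count()
    for m in metrics:
        out[f"n_{m}"] = counts[m]
    return out.reset_index()


def replicate_cv(records: pd.DataFrame, metrics, by=("sample_id", "variant")) -> pd.DataFrame:
    """Coefficient of variation of replicates: sd(ddof=1) / mean.

    The sign follows the mean, so metrics with negative means (like the BA
    ratio) yield negative CVs.  Requires >= 2 defined replicates; a zero mean
    leaves the CV undefined (NaN).
    """
    by = list(by)
    g = records.groupby(by, sort=False)
    mean = g[list(metrics)].mean()
    sd = g[list(metrics)].std(ddof=1)
    n = g[list(metrics)].count()
    cv = sd / mean
    cv[(n < 2) | (mean == 0)] = np.nan
    return cv.reset_index()


def pearson(x, y):
    """Pearson r and R^2 with pairwise deletion of missing values.

    Returns ``(nan, nan)`` when fewer than 3 complete pairs remain or either
    variable is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value.

    When every observation is identical the statistic is 0 and p is 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_control(groups: dict, control: str, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's joint-ranks test of each group against a designated control.

    z statistics use the tie-corrected joint-rank variance; two-sided normal
    p-values get a Bonferroni factor equal to the number of comparisons
    (k - 1).  Returns a DataFrame indexed by group with columns
    ``z, p, p_adjusted``.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for lab, arr in zip(labels, arrays):
        mean_ranks[lab] = float(np.mean(ranks[start : start + arr.size]))
        sizes[lab] = arr.size
        start += arr.size
    tie = _tie_term(pooled)
    base_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    k = len(labels)
    rows = []
    for lab in labels:
        if lab == control:
            continue
        se = math.sqrt(base_var * (1.0 / sizes[lab] + 1.0 / sizes[control]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[lab] - mean_ranks[control]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * (k - 1)) if adjust == "bonferroni" else p
        rows.append({"group": lab, "z": z, "p": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# permutational factorial ANOVA
# ---------------------------------------------------------------------------


def _sum_coding(values: np.ndarray):
    """Sum-to-zero contrast columns for one categorical factor."""
    levels = np.unique(values)
    k = len(levels)
    cols = np.zeros((values.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[values == lev, j] = 1.0
    cols[values == levels[-1], :] = -1.0
    return cols, levels


@dataclass
class PermutationAnovaResults:
    """Fitted permutation-ANOVA effects.

    ``effects`` is a DataFrame indexed by effect with columns
    ``df, ss, F, eta_p_sq, p_perm``; ``eta_p_sq`` is
    SS_effect / (SS_effect + SS_error) from the OLS decomposition.
    """

    effects: pd.DataFrame
    ss_error: float
    df_error: int
    n_obs: int
    n_perm: int
    method: str = "freedman-lane"
    ss_type: str = "III (sum-to-zero)"
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            "Permutational factorial ANOVA",
            f"  n = {self.n_obs}, permutations = {self.n_perm}, "
            f"method = {self.method}, SS = {self.ss_type}",
            "",
            self.effects.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            f"  residual: SS = {self.ss_error:.4f} on {self.df_error} df",
        ]
        return "\n".join(lines)


class PermutationAnova:
    """Fully crossed fixed-effects factorial model with permutation inference.

    Parameters
    ----------
    data : DataFrame
        Tidy table with one row per observation.
    response : str
        Column holding the response variable.
    factors : sequence of str
        Categorical factor columns; all main effects and interactions up to
        the full order are tested.

    An empty cell in the crossing raises a ValueError naming the cell.
    """

    def __init__(self, data: pd.DataFrame, response: str, factors=DEFAULT_FACTORS):
        self.factors = tuple(factors)
        sub = data.loc[:, list(self.factors) + [response]].dropna()
        self.y = sub[response].to_numpy(dtype=np.float64)
        n = self.y.size
        codes = {}
        level_values = {}
        for f in self.factors:
            codes[f], level_values[f] = _sum_coding(sub[f].to_numpy())
        # check the full crossing for empty cells
        counts = sub.groupby(list(self.factors), observed=False).size()
        full = list(itertools.product(*[level_values[f] for f in self.factors]))
        for cell in full:
            key = cell if len(cell) > 1 else cell[0]
            if key not in counts.index or counts.loc[key] == 0:
                raise ValueError(f"empty cell in factorial crossing: {dict(zip(self.factors, cell))}")

        self.effect_names = []
        self.effect_cols = {}
        for order in range(1, len(self.factors) + 1):
            for combo in itertools.combinations(self.factors, order):
                name = ":".join(combo)
                block = codes[combo[0]]
                for f in combo[1:]:
                    block = np.einsum("ni,nj->nij", block, codes[f]).reshape(n, -1)
                self.effect_names.append(name)
                self.effect_cols[name] = block
        self.X = np.hstack([np.ones((n, 1))] + [self.effect_cols[e] for e in self.effect_names])
        self._Q_full = np.linalg.qr(self.X, mode="reduced")[0]
        self._Q_reduced = {}
        for e in self.effect_names:
            keep = [np.ones((n, 1))] + [self.effect_cols[k] for k in self.effect_names if k != e]
            self._Q_reduced[e] = np.linalg.qr(np.hstack(keep), mode="reduced")[0]
        self.df_error = n - self.X.shape[1]
        if self.df_error <= 0:
            raise ValueError("model is saturated: no residual degrees of freedom")

    @staticmethod
    def _sse(Q, Y):
        proj = Q.T @ Y
        return np.einsum("i...,i...->...", Y, Y) - np.einsum("i...,i...->...", proj, proj)

    def fit(self, n_perm: int = 1000, seed=None, exhaustive: bool = False) -> PermutationAnovaResults:
        """Run the permutation test.

        ``exhaustive=True`` enumerates every permutation of the observations
        (only sensible for n <= 9); otherwise ``n_perm`` random permutations
        are sampled and p = (b + 1)/(n_perm + 1) with b the number of
        permuted statistics >= the observed one.
        """
        y = self.y
        n = y.size
        if exhaustive:
            perms = np.array(list(itertools.permutations(range(n))))
            n_perm = perms.shape[0]
        else:
            if n_perm < 99:
                raise ValueError("n_perm must be >= 99")
            rng = np.random.default_rng(seed)
            perms = np.argsort(rng.random((n_perm, n)), axis=1)

        sse_full_obs = float(self._sse(self._Q_full, y))
        rows = []
        for e in self.effect_names:
            Qr = self._Q_reduced[e]
            df_e = self.effect_cols[e].shape[1]
            ss_e = float(self._sse(Qr, y)) - sse_full_obs
            F_obs = (ss_e / df_e) / (sse_full_obs / self.df_error)
            eta = ss_e / (ss_e + sse_full_obs)

            fitted = Qr @ (Qr.T @ y)
            resid = y - fitted
            Ystar = fitted[:, None] + resid[perms].T  # n x n_perm
            sse_red = self._sse(Qr, Ystar)
            sse_full = self._sse(self._Q_full, Ystar)
            F_star = ((sse_red - sse_full) / df_e) / (sse_full / self.df_error)
            if exhaustive:
                # the identity permutation is part of the enumeration
                p = float(np.mean(F_star >= F_obs - 1e-12))
            else:
                b = int(np.sum(F_star >= F_obs - 1e-12))
                p = (b + 1) / (n_perm + 1)
            rows.append({"effect": e, "df": df_e, "ss": ss_e, "F": F_obs,
                         "eta_p_sq": eta, "p_perm": p})
        effects = pd.DataFrame(rows).set_index("effect")
        return PermutationAnovaResults(
            effects=effects, ss_error=sse_full_obs, df_error=self.df_error,
            n_obs=n, n_perm=n_perm, seed=seed,
        )


def perm_anova(table: pd.DataFrame, response: str, n_perm: int = 1000, seed=None,
               factors=DEFAULT_FACTORS, exhaustive: bool = False) -> PermutationAnovaResults:
    """Functional wrapper: ``PermutationAnova(table, response, factors).fit(...)``."""
    return PermutationAnova(table, response, factors=factors).fit(
        n_perm=n_perm, seed=seed, exhaustive=exhaustive
    )


# ---------------------------------------------------------------------------
# sensitivity report
# ---------------------------------------------------------------------------


def significance_symbol(p: float, alphas=(0.05, 0.01, 0.001)) -> str:
    if not np.isfinite(p):
        return "NS"
    if p <= alphas[2]:
        return "***"
    if p <= alphas[1]:
        return "**"
    if p <= alphas[0]:
        return "*"
    return "NS"


def sensitivity_report(records: pd.DataFrame, metrics, control: str = "JPG",
                       variant_col: str = "variant", alphas=(0.05, 0.01, 0.001)):
    """Median-by-variant table with Kruskal-Wallis and Dunn-vs-control flags.

    Returns ``(medians, flags, kw)``: medians per variant x metric, the
    Dunn-vs-control significance symbols (control row marked '-'), and the
    omnibus Kruskal-Wallis symbol per metric.  The same call serves both the
    metric-median and the replicate-CV analyses; dispatch on the values you
    pass in.
    """
    variants = list(records[variant_col].unique())
    if control not in variants:
        raise ValueError(f"control variant {control!r} not present")
    medians = records.groupby(variant_col, sort=False)[list(metrics)].median().reindex(variants)
    flags = pd.DataFrame("-", index=variants, columns=list(metrics))
    kw = {}
    for m in metrics:
        groups = {v: records.loc[records[variant_col] == v, m].dropna().to_numpy() for v in variants}
        groups = {v: g for v, g in groups.items() if g.size > 0}
        if len(groups) < 2 or control not in groups:
            kw[m] = "NS"
            continue
        _, p_kw = kruskal_wallis(list(groups.values()))
        kw[m] = significance_symbol(p_kw, alphas)
        dunn = dunn_control(groups, control)
        for v in variants:
            if v == control:
                continue
            if v in dunn.index:
                flags.loc[v, m] = significance_symbol(float(dunn.loc[v, "p_adjusted"]), alphas)
            else:
                flags.loc[v, m] = "NS"
    kw = pd.Series(kw, name="kruskal_wallis")
    return medians, flags, kw
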