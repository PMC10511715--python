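"""Outcome validation of patient phenotypes.

Pairwise cluster contrasts use the exact tests standard for small-sample
clinical tables: Fisher's exact test (two-sided, sum of all tables with
fixed margins no more probable than the observed one) for binary outcomes
and the Wilcoxon rank-sum test for continuous outcomes, with Holm step-down
adjustment applied within each outcome's family of C(k, 2) comparisons.  A
distance-based permutation MANOVA (pseudo-F on squared Euclidean distances
of column-standardized outcomes) tests all outcomes simultaneously.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import BINARY_OUTCOMES, CONTINUOUS_OUTCOMES

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "PairwiseTestTable",
    "pairwise_outcome_tests",
    "PermanovaResult",
    "permutation_manova",
    "ClusterSummary",
    "summarize_clusters",
]

#: exact enumeration below this total sample size, normal approximation above
_EXACT_N = 12


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    The two-sided p is the sum of hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (the convention shared by the major statistical
    ecosystems).  A table with a zero margin admits only itself, giving
    p = 1 rather than an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` with midranks for ties.
    The p-value is exact (full enumeration over rank assignments) when
    n + m <= 12 with no ties, and a tie- and continuity-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    W = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank sum of x
    return W, float(res.pvalue)


def wilcoxon_signed_rank(d) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped first; exact sign-pattern enumeration for
    n <= 12 without tied magnitudes, normal approximation with continuity
    correction otherwise.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank undefined")
    mags = np.abs(d)
    has_ties = np.unique(mags).size < mags.size
    method = "exact" if (d.size <= _EXACT_N and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    adjusted_(j) = max_{i<=j} min(1, (m - i + 1) * p_(i)) over the ascending
    order statistics p_(i).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# pairwise cluster x outcome table
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTestTable:
    """Long-format pairwise results plus a Table-5-style wide view."""

    long: pd.DataFrame  # cluster_a, cluster_b, outcome, test, statistic, p_raw, p_holm, direction, note
    alpha: float = 0.05

    def wide(self, column: str = "p_holm") -> pd.DataFrame:
        w = self.long.pivot_table(
            index=["cluster_a", "cluster_b"], columns="outcome", values=column, aggfunc="first"
        )
        order = [c for c in CONTINUOUS_OUTCOMES + BINARY_OUTCOMES if c in w.columns]
        return w[order]

    def significant(self) -> pd.DataFrame:
        return self.long[self.long["p_holm"] < self.alpha].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.long.to_csv(path, sep="\t", index=False)


def pairwise_outcome_tests(
    labels, outcomes: pd.DataFrame, alpha: float = 0.05,
    binary_outcomes=None, continuous_outcomes=None,
) -> PairwiseTestTable:
    """Pairwise cluster contrasts for every outcome with Holm adjustment.

    Continuous outcomes (lengths of stay, support durations, severity
    scores) use the rank-sum test; binary outcomes (death, AKI, delirium,
    MV presence, fluid overload) use Fisher's exact test on the 2x2 table.
    Holm is applied within each outcome across all cluster pairs.  A pair
    with a degenerate cluster (n < 2) is flagged in the ``note`` column
    rather than dropped.
    """
    labels = pd.Series(labels)
    if labels.index.equals(pd.RangeIndex(len(labels))) and "patient_id" in outcomes.columns:
        labels.index = outcomes["patient_id"].values
    outcomes = outcomes.set_index("patient_id") if "patient_id" in outcomes.columns else outcomes
    outcomes = outcomes.loc[labels.index]
    binary_outcomes = [c for c in (binary_outcomes or BINARY_OUTCOMES) if c in outcomes.columns]
    continuous_outcomes = [c for c in (continuous_outcomes or CONTINUOUS_OUTCOMES) if c in outcomes.columns]

    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for pairwise tests")
    pairs = list(itertools.combinations(clusters, 2))
    groups = {c: outcomes[labels == c] for c in clusters}

    rows = []
    for outcome in continuous_outcomes + binary_outcomes:
        kind = "fisher_exact" if outcome in binary_outcomes else "wilcoxon_rank_sum"
        for a, b in pairs:
            ga, gb = groups[a][outcome].to_numpy(float), groups[b][outcome].to_numpy(float)
            note = ""
            if ga.size < 2 or gb.size < 2:
                rows.append((a, b, outcome, kind, np.nan, np.nan, "", "degenerate cluster (n<2)"))
                continue
            if kind == "fisher_exact":
                table = [
                    [int(ga.sum()), int(ga.size - ga.sum())],
                    [int(gb.sum()), int(gb.size - gb.sum())],
                ]
                p = fisher_exact_2x2(table)
                stat = float(table[0][0])
                direction = ">" if ga.mean() > gb.mean() else ("<" if ga.mean() < gb.mean() else "=")
            else:
                stat, p = wilcoxon_rank_sum(ga, gb)
                ma, mb = np.median(ga), np.median(gb)
                direction = ">" if ma > mb else ("<" if ma < mb else "=")
            rows.append((a, b, outcome, kind, stat, p, direction, note))

    long = pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "outcome", "test", "statistic", "p_raw", "direction", "note"],
    )
    long["p_holm"] = np.nan
    for outcome in long["outcome"].unique():
        sel = (long["outcome"] == outcome) & long["p_raw"].notna()
        if sel.any():
            long.loc[sel, "p_holm"] = holm_adjust(long.loc[sel, "p_raw"].to_numpy())
    long = long[
        ["cluster_a", "cluster_b", "outcome", "test", "statistic", "p_raw", "p_holm", "direction", "note"]
    ]
    return PairwiseTestTable(long=long, alpha=alpha)


# ---------------------------------------------------------------------------
# permutation MANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Distance-based permutation MANOVA result (pseudo-F and SS terms)."""

    pseudo_F: float
    SS_among: float
    SS_within: float
    SS_total: float
    df_among: int
    df_within: int
    n_permutations: int
    p_value: float
    seed: int
    standardize: str = "zscore"

    def __str__(self) -> str:
        return (
            "Permutation MANOVA\n"
            f"pseudo-F = {self.pseudo_F:.4f}  (df {self.df_among}, {self.df_within})\n"
            f"SS among = {self.SS_among:.4f}  SS within = {self.SS_within:.4f}  "
            f"SS total = {self.SS_total:.4f}\n"
            f"p = {self.p_value:.4g}  ({self.n_permutations} permutations, seed {self.seed}, "
            f"standardize={self.standardize})"
        )


def _ss_terms(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and 0-based labels.

    Uses u_g' D2 u_g / (2 n_g) per group via one matmul so the permutation
    loop stays O(N^2 k) in vectorized numpy.
    """
    N = D2.shape[0]
    k = int(labels.max()) + 1
    U = np.zeros((N, k))
    U[np.arange(N), labels] = 1.0
    n_g = U.sum(axis=0)
    block = np.einsum("ng,ng->g", U, D2 @ U)  # u_g' D2 u_g, pairs counted twice
    ss_total = D2.sum() / (2 * N)
    ss_within = float((block / (2 * n_g)).sum())
    return float(ss_total), ss_within


def permutation_manova(
    outcome_matrix,
    labels,
    n_permutations: int = 9999,
    seed: int = 0,
    standardize: str = "zscore",
) -> PermanovaResult:
    """Distance-based permutation MANOVA across patient clusters.

    Outcomes are z-scored per column (``standardize="zscore"``, the
    default) or used raw; squared Euclidean distances d_ij^2 give

        SS_total  = (1/N) sum_{i<j} d_ij^2
        SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
        pseudo-F  = (SS_among / (k-1)) / (SS_within / (N-k))

    and the p-value is the permutation tail probability
    (1 + #{F_perm >= F_obs}) / (n_permutations + 1) over seeded label
    permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if standardize not in ("zscore", "raw"):
        raise ValueError(f"unknown standardize option {standardize!r}")
    Y = np.asarray(
        outcome_matrix.to_numpy() if hasattr(outcome_matrix, "to_numpy") else outcome_matrix,
        dtype=float,
    )
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(pd.factorize(np.asarray(labels))[0])
    N = Y.shape[0]
    if labels.shape[0] != N:
        raise ValueError("labels and outcome matrix have different lengths")
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if (counts == 0).any():
        raise ValueError("empty cluster")
    if standardize == "zscore":
        sd = Y.std(axis=0, ddof=1)
        mean = Y.mean(axis=0)
        keep = sd > 0
        Y = (Y[:, keep] - mean[keep]) / sd[keep]
        if Y.shape[1] == 0:
            raise ValueError("all outcome columns are constant")

    sq = (Y**2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * Y @ Y.T, 0.0)
    np.fill_diagonal(D2, 0.0)

    ss_total, ss_within = _ss_terms(D2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, N - k
    F_obs = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(labels)
        _, ss_w = _ss_terms(D2, perm)
        ss_a = ss_total - ss_w
        F = (ss_a / df_among) / (ss_w / df_within) if ss_w > 0 else np.inf
        if F >= F_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_permutations + 1)

    return PermanovaResult(
        pseudo_F=float(F_obs) if np.isfinite(F_obs) else float("inf"),
        SS_among=float(ss_among),
        SS_within=float(ss_within),
        SS_total=float(ss_total),
        df_among=df_among,
        df_within=df_within,
        n_permutations=int(n_permutations),
        p_value=float(p),
        seed=int(seed),
        standardize=standardize,
    )


# ---------------------------------------------------------------------------
# cluster summaries
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    """Formatted per-cluster outcome summary plus numeric accessors."""

    table: pd.DataFrame  # rows: outcomes, columns: clusters, formatted cells
    counts: pd.Series
    continuous_stats: pd.DataFrame  # MultiIndex (outcome, stat) x cluster
    binary_stats: pd.DataFrame  # MultiIndex (outcome, stat) x cluster
    feature_means: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="outcome")


def summarize_clusters(labels, outcomes: pd.DataFrame, features=None) -> ClusterSummary:
    """Per-cluster descriptive table: mean +/- SD for continuous outcomes,
    n (%) for binary outcomes, plus mean feature distributions if given.

    Percentages are printed to two decimals (a cluster of four with one
    death reads "1 (25.00)").
    """
    labels = pd.Series(labels)
    if labels.index.equals(pd.RangeIndex(len(labels))) and "patient_id" in outcomes.columns:
        labels.index = outcomes["patient_id"].values
    outcomes = outcomes.set_index("patient_id") if "patient_id" in outcomes.columns else outcomes
    outcomes = outcomes.loc[labels.index]
    clusters = sorted(pd.unique(labels))
    counts = pd.Series({c: int((labels == c).sum()) for c in clusters}, name="n")

    cont = [c for c in CONTINUOUS_OUTCOMES if c in outcomes.columns]
    binr = [c for c in BINARY_OUTCOMES if c in outcomes.columns]

    rows: dict[str, dict] = {}
    cont_stats, bin_stats = {}, {}
    for c in clusters:
        sub = outcomes[labels == c]
        col = {}
        for o in cont:
            m, s = sub[o].mean(), sub[o].std(ddof=1)
            col[o] = f"{m:.1f} ± {s:.1f}"
            cont_stats[(o, "mean", c)] = m
            cont_stats[(o, "sd", c)] = s
        for o in binr:
            n_pos = int(sub[o].sum())
            pct = 100.0 * n_pos / len(sub)
            col[o] = f"{n_pos} ({pct:.2f})"
            bin_stats[(o, "count", c)] = n_pos
            bin_stats[(o, "pct", c)] = pct
        rows[c] = col

    table = pd.DataFrame(rows)
    table.columns = [f"cluster {c} (N = {counts[c]})" for c in clusters]

    def unstack(d):
        if not d:
            return pd.DataFrame()
        s = pd.Series(d)
        s.index = pd.MultiIndex.from_tuples(s.index, names=["outcome", "stat", "cluster"])
        return s.unstack("cluster")

    feature_means = None
    if features is not None:
        X = features.values if hasattr(features, "values") else features
        X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
        feature_means = X.groupby(labels.values).mean().rename_axis("cluster")

    return ClusterSummary(
        table=table,
        counts=counts,
        continuous_stats=unstack(cont_stats),
        binary_stats=unstack(bin_stats),
        feature_means=feature_means,
    )
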