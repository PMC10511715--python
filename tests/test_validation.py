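"""Statistical kernels vs independent enumeration oracles; summary tables."""

import numpy as np
import pandas as pd
import pytest

from medpheno import (
    fisher_exact_2x2,
    holm_adjust,
    pairwise_outcome_tests,
    permutation_manova,
    summarize_clusters,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from _oracles import fisher_oracle, permanova_oracle, ranksum_oracle, signed_rank_oracle


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        assert fisher_exact_2x2([[1, 9], [9, 1]]) == pytest.approx(
            fisher_oracle(1, 9, 9, 1), rel=1e-9
        )

    def test_enumeration_sweep_all_small_tables(self):
        """Every 2x2 table with total n <= 10 agrees with the exact rational
        hypergeometric enumeration oracle."""
        for n in range(1, 11):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        p = fisher_exact_2x2([[a, b], [c, d]])
                        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12), (
                            a, b, c, d
                        )
                        assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 4], [0, 6]]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_interleaved_samples(self):
        _, p = wilcoxon_rank_sum([1, 3, 5], [2, 4, 6])
        assert p == pytest.approx(0.7)

    def test_most_extreme_split(self):
        _, p = wilcoxon_rank_sum([1, 2], [100, 101])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1, 2])

    def test_enumeration_sweep(self):
        """Untied samples with n + m <= 10 agree with complete enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 11 - n))
            vals = rng.permutation(20)[: n + m].astype(float)
            x, y = vals[:n], vals[n:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(ranksum_oracle(x, y), abs=1e-9)


class TestSignedRank:
    def test_all_positive_three(self):
        _, p = wilcoxon_signed_rank([1, 2, 3])
        assert p == pytest.approx(2 / 8)  # two-sided: both all-positive patterns

    def test_symmetric_pair(self):
        _, p = wilcoxon_signed_rank([-1, 1])
        assert p == pytest.approx(1.0)

    def test_zero_dropped(self):
        _, p = wilcoxon_signed_rank([0, 2])
        assert p == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0, 0])

    def test_enumeration_sweep(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            d = rng.permutation(30)[:n].astype(float) + 0.5
            signs = rng.choice([-1, 1], size=n)
            d = d * signs
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(signed_rank_oracle(d), abs=1e-9)


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

class TestHolm:
    def test_single_p_identity(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_hand_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])

    def test_preserves_input_order(self):
        np.testing.assert_allclose(holm_adjust([0.03, 0.01, 0.02]), [0.04, 0.03, 0.04])

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(8)
            adj = holm_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0 + 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()
            # smallest p gets the Bonferroni factor m
            assert adj[order[0]] == pytest.approx(min(1.0, 8 * p[order[0]]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def test_separated_groups_match_enumeration(self):
        """A = {0,0,0}, B = {10,10,10}: only the 2 separating assignments of
        the 20 reach the observed F, so exact p = 0.1."""
        Y = np.array([0, 0, 0, 10, 10, 10.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        p_exact, _ = permanova_oracle(Y, labels)
        assert p_exact == pytest.approx(0.1)
        res = permutation_manova(Y, labels, n_permutations=9999, seed=3, standardize="raw")
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_identical_groups(self):
        Y = np.array([[1.0, 2], [3, 4], [5, 6], [1, 2], [3, 4], [5, 6]])
        res = permutation_manova(Y, [0, 0, 0, 1, 1, 1], n_permutations=999, seed=0, standardize="raw")
        assert res.SS_among == pytest.approx(0.0, abs=1e-9)
        assert res.pseudo_F == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_ss_decomposition_additive(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(24, 4))
        labels = rng.integers(0, 3, size=24)
        res = permutation_manova(Y, labels, n_permutations=99, seed=0)
        assert res.SS_total == pytest.approx(res.SS_among + res.SS_within, rel=1e-9)
        assert res.df_among == len(np.unique(labels)) - 1
        assert res.df_within == 24 - len(np.unique(labels))

    def test_enumeration_agreement_small_inputs(self):
        """Random <= 8-point inputs: permutation p matches the exhaustive
        enumeration oracle within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            N = int(rng.integers(6, 9))
            Y = rng.normal(size=(N, 2))
            labels = np.array([0] * (N // 2) + [1] * (N - N // 2))
            p_exact, F_exact = permanova_oracle(Y, labels)
            res = permutation_manova(Y, labels, n_permutations=4999, seed=trial, standardize="raw")
            assert res.pseudo_F == pytest.approx(F_exact, rel=1e-9)
            se = np.sqrt(p_exact * (1 - p_exact) / 4999)
            assert res.p_value == pytest.approx(p_exact, abs=4 * se + 2e-3)

    def test_matches_scikit_bio(self):
        """Independent cross-check of the pseudo-F against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        Y = rng.normal(size=(20, 3))
        labels = rng.integers(0, 2, size=20).astype(str)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(Y)))
        ref = skbio_stats.permanova(dm, labels, permutations=99)
        res = permutation_manova(Y, labels, n_permutations=99, seed=0, standardize="raw")
        assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="clusters"):
            permutation_manova(np.zeros((4, 2)), [0, 0, 0, 0], n_permutations=9)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_manova(np.zeros((4, 2)), [0, 0, 1, 1], n_permutations=0)


# ---------------------------------------------------------------------------
# pairwise table & summaries
# ---------------------------------------------------------------------------

def cohort_from_death_counts(counts):
    """Per-patient labels + mortality from per-cluster (deaths, n)."""
    labels, deaths = [], []
    for cl, (d, n) in enumerate(counts, start=1):
        labels += [cl] * n
        deaths += [1] * d + [0] * (n - d)
    ids = [f"P{i}" for i in range(len(labels))]
    outcomes = pd.DataFrame({"patient_id": ids, "mortality": deaths})
    return pd.Series(labels, index=ids), outcomes


TABLE3_DEATHS = [(6, 234), (18, 201), (3, 115), (54, 247), (16, 194)]


class TestPairwiseTable:
    def test_death_column_reproduces_published_contrasts(self):
        """Five clusters with deaths 6/234, 18/201, 3/115, 54/247, 16/194:
        Holm-adjusted Fisher p-values hit the published 2-4 and 4-5 values."""
        labels, outcomes = cohort_from_death_counts(TABLE3_DEATHS)
        table = pairwise_outcome_tests(labels, outcomes)
        long = table.long.set_index(["cluster_a", "cluster_b"])
        assert round(long.loc[(2, 4), "p_holm"], 4) == 0.0018
        assert round(long.loc[(4, 5), "p_holm"], 4) == 0.0009
        assert round(long.loc[(1, 3), "p_holm"], 4) == 1.0

    def test_all_zero_binary_outcome(self):
        labels = pd.Series([1] * 5 + [2] * 5, index=[f"P{i}" for i in range(10)])
        outcomes = pd.DataFrame({"patient_id": labels.index, "aki": [0] * 10})
        table = pairwise_outcome_tests(labels, outcomes)
        assert table.long["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_cluster_flagged_not_dropped(self):
        labels = pd.Series([1] * 6 + [2], index=[f"P{i}" for i in range(7)])
        outcomes = pd.DataFrame(
            {"patient_id": labels.index, "mortality": [0, 1, 0, 1, 0, 1, 0]}
        )
        table = pairwise_outcome_tests(labels, outcomes)
        row = table.long.iloc[0]
        assert "degenerate" in row["note"]
        assert np.isnan(row["p_raw"])

    def test_holm_within_outcome_only(self):
        """Adjustment families are per-outcome: each outcome's adjusted
        values depend only on that outcome's raw values."""
        rng = np.random.default_rng(7)
        ids = [f"P{i}" for i in range(60)]
        labels = pd.Series(rng.integers(1, 4, size=60), index=ids)
        outcomes = pd.DataFrame(
            {
                "patient_id": ids,
                "mortality": rng.integers(0, 2, size=60),
                "icu_los_days": rng.exponential(5, size=60),
            }
        )
        table = pairwise_outcome_tests(labels, outcomes)
        for outcome in ("mortality", "icu_los_days"):
            sub = table.long[table.long["outcome"] == outcome]
            np.testing.assert_allclose(
                sub["p_holm"].to_numpy(), holm_adjust(sub["p_raw"].to_numpy())
            )
        assert (table.long["p_holm"] >= table.long["p_raw"] - 1e-15).all()

    def test_continuous_outcomes_use_rank_sum(self):
        labels, outcomes = cohort_from_death_counts([(2, 10), (3, 10)])
        outcomes["icu_los_days"] = np.arange(20, dtype=float)
        table = pairwise_outcome_tests(labels, outcomes)
        tests = table.long.set_index("outcome")["test"]
        assert tests.loc["mortality"] == "fisher_exact"
        assert tests.loc["icu_los_days"] == "wilcoxon_rank_sum"


class TestSummaries:
    def test_quarter_mortality_formatting(self):
        labels = pd.Series([1, 1, 1, 1], index=list("ABCD"))
        outcomes = pd.DataFrame({"patient_id": list("ABCD"), "mortality": [1, 0, 0, 0]})
        summary = summarize_clusters(labels, outcomes)
        assert summary.table.loc["mortality"].iloc[0] == "1 (25.00)"

    def test_published_mortality_row(self):
        """Death counts 6/234 ... render as the published per-cluster cells."""
        labels, outcomes = cohort_from_death_counts(TABLE3_DEATHS)
        summary = summarize_clusters(labels, outcomes)
        cells = summary.table.loc["mortality"].tolist()
        assert cells == ["6 (2.56)", "18 (8.96)", "3 (2.61)", "54 (21.86)", "16 (8.25)"]

    def test_archetype_mortality_cross_check(self, planted_cohort):
        """Per-archetype mortality in the summary stays within 3 SE of the
        generator parameters."""
        from medpheno import recode_outcomes

        spec, _, outcomes, truth = planted_cohort
        oc = recode_outcomes(outcomes)
        labels = truth.patient_archetype
        summary = summarize_clusters(labels, oc)
        for a in range(1, spec.n_archetypes + 1):
            p = spec.outcome_params.mortality[a - 1]
            n = summary.counts[a]
            pct = summary.binary_stats.loc[("mortality", "pct"), a] / 100.0
            assert abs(pct - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_continuous_mean_sd_cells(self):
        labels = pd.Series([1, 1, 2, 2], index=list("ABCD"))
        outcomes = pd.DataFrame(
            {"patient_id": list("ABCD"), "icu_los_days": [2.0, 4.0, 10.0, 10.0]}
        )
        summary = summarize_clusters(labels, outcomes)
        assert summary.table.loc["icu_los_days"].tolist() == ["3.0 ± 1.4", "10.0 ± 0.0"]
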