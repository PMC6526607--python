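import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import cooccurnet as cn
from cooccurnet.association import (
    AssociationConfig,
    bh_adjust,
    browns_merge,
    build_edges,
    covariance_from_nulls,
    estimate_measure_covariance,
    filter_prevalent,
    pairwise_scores,
    permutation_pvalues,
    relative_abundance,
)


def _table(rows, prefix="t"):
    arr = np.asarray(rows)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestPairwiseScores:
    def test_identical_profiles_score_one_everywhere(self):
        t = _table([[1, 2, 3, 4], [1, 2, 3, 4], [9, 9, 9, 10]])
        scores, _ = pairwise_scores(t)
        for m in ("pearson", "spearman", "bray_curtis", "kld"):
            assert scores[m].iloc[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_exact_reversal_gives_minus_one(self):
        # constant filler keeps column sums equal, so relative abundances
        # stay proportional to the counts
        t = _table([[1, 2, 3, 4], [4, 3, 2, 1], [5, 5, 5, 5]])
        scores, _ = pairwise_scores(t)
        assert scores["pearson"].iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert scores["spearman"].iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_correlations_match_scipy(self, rng):
        from scipy.stats import pearsonr, spearmanr

        t = _table(rng.integers(1, 100, size=(6, 12)))
        rel = relative_abundance(t)
        scores, _ = pairwise_scores(t)
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            assert scores["pearson"].iloc[i, j] == pytest.approx(
                pearsonr(rel.iloc[i], rel.iloc[j]).statistic, abs=1e-12
            )
            assert scores["spearman"].iloc[i, j] == pytest.approx(
                spearmanr(rel.iloc[i], rel.iloc[j]).statistic, abs=1e-12
            )

    def test_kld_hand_example(self):
        # profiles [.5,.5] vs [.9,.1]; direct evaluation of the
        # symmetrized KL formula against the vectorized engine
        from cooccurnet.association import _Engine

        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        sym = 0.5 * ((p * np.log(p / q)).sum() + (q * np.log(q / p)).sum())
        eng = _Engine(np.vstack([p, q]), ("kld",), pseudocount=1e-9)
        assert eng.scores()["kld"][0, 1] == pytest.approx(np.exp(-sym), abs=1e-6)

    def test_kld_on_table_matches_formula(self, rng):
        t = _table(rng.integers(1, 60, size=(4, 6)))
        rel = relative_abundance(t).to_numpy()
        scores, _ = pairwise_scores(t)
        prof = rel + 1e-6
        prof = prof / prof.sum(axis=1, keepdims=True)
        a, b = prof[1], prof[3]
        sym = 0.5 * ((a * np.log(a / b)).sum() + (b * np.log(b / a)).sum())
        assert scores["kld"].iloc[1, 3] == pytest.approx(np.exp(-sym), abs=1e-10)

    def test_zero_variance_taxon_flagged_not_raised(self):
        # equal column sums keep the constant-count row constant in
        # relative abundance too
        t = _table([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]])
        scores, flagged = pairwise_scores(t)
        assert flagged == ["t0"]
        assert scores["pearson"].loc["t0", "t1"] == 0.0
        assert scores["spearman"].loc["t0", "t2"] == 0.0

    def test_requires_four_samples(self):
        with pytest.raises(ValueError):
            pairwise_scores(_table([[1, 2, 3], [3, 2, 1]]))


class TestPermutationPvalues:
    def test_constant_taxon_scores_p_one(self):
        # equal column sums keep t0 constant in relative abundance
        t = _table([[5, 5, 5, 5, 5], [1, 9, 4, 2, 8], [14, 6, 11, 13, 7]])
        p = permutation_pvalues(t, "pearson", n_permutations=200, seed=0)
        assert p.loc["t0", "t1"] == 1.0
        assert p.loc["t0", "t2"] == 1.0

    def test_perfect_pair_attains_floor(self, rng):
        base = rng.integers(10, 60, size=20)
        filler = rng.integers(20, 80, size=(3, 20))
        t = _table(np.vstack([base, 2 * base, filler]))
        p = permutation_pvalues(t, "pearson", n_permutations=999, seed=1)
        assert p.loc["t0", "t1"] == pytest.approx(1 / 1000)
        p = permutation_pvalues(t, "spearman", n_permutations=999, seed=1)
        assert p.loc["t0", "t1"] == pytest.approx(1 / 1000)

    def test_null_pvalues_are_uniform(self, rng):
        """Independent taxa: two-sided permutation p over ~2000 pairs is
        uniform by Kolmogorov-Smirnov at alpha=0.01."""
        t = _table(rng.poisson(100, size=(64, 20)) + 1)
        p = permutation_pvalues(t, "pearson", n_permutations=999, seed=3)
        iu = np.triu_indices(64, 1)
        assert kstest(p.to_numpy()[iu], "uniform").pvalue > 0.01

    def test_requires_99_permutations(self):
        t = _table([[1, 2, 3, 4], [4, 3, 2, 1]])
        with pytest.raises(ValueError):
            permutation_pvalues(t, "pearson", n_permutations=50)


class TestBrownsMerge:
    def test_single_p_passes_through(self):
        assert browns_merge([0.123], [[4.0]]) == pytest.approx(0.123)

    def test_all_ones_merge_to_one(self):
        assert browns_merge([1.0, 1.0, 1.0], np.zeros((3, 3))) == pytest.approx(1.0)

    def test_independence_limit_is_fisher(self):
        from scipy.stats import chi2

        p = [0.05, 0.05]
        fisher = chi2.sf(-2 * np.sum(np.log(p)), 4)
        assert browns_merge(p, np.zeros((2, 2))) == pytest.approx(fisher, abs=1e-12)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            browns_merge([0.1, 0.1], [[1.0, 5.0], [5.0, 1.0]])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            browns_merge([0.0, 0.5], np.zeros((2, 2)))


class TestMeasureCovariance:
    def test_duplicated_measure_has_full_correlation(self, rng):
        v = rng.normal(size=(500, 50))
        cov = covariance_from_nulls({"a": v, "b": v.copy()})
        assert cov.loc["a", "b"] == pytest.approx(cov.loc["a", "a"], rel=1e-9)

    def test_independent_measures_have_near_zero_covariance(self, rng):
        cov = covariance_from_nulls(
            {"a": rng.normal(size=(500, 50)), "b": rng.normal(size=(500, 50))}
        )
        se = 4.0 / np.sqrt(500 * 50)
        assert abs(cov.loc["a", "b"]) < 3 * se + 0.05

    def test_single_measure_variance_is_chi_square_two(self, rng):
        cov = covariance_from_nulls({"a": rng.normal(size=(1000, 100))})
        assert cov.loc["a", "a"] == pytest.approx(4.0, rel=0.15)

    def test_requires_100_replicates(self, rng):
        with pytest.raises(ValueError):
            covariance_from_nulls({"a": rng.normal(size=(50, 10))})

    def test_estimated_from_table_is_psd_with_chi2_diagonal(self, planted):
        cfg = AssociationConfig(seed=0, n_permutations=200)
        cov = estimate_measure_covariance(planted["table"].iloc[:30], cfg, n_pool=50)
        w = np.linalg.eigvalsh(cov.to_numpy())
        assert w.min() >= -1e-10
        assert np.allclose(np.diag(cov), 4.0, rtol=0.4)


class TestBHAdjust:
    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04], m=4), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=40)
        np.testing.assert_allclose(
            bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_dominates_input_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1).all()
        # reapplication can only push q-values further toward 1
        assert (bh_adjust(q) >= q - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_explicit_larger_universe(self):
        np.testing.assert_allclose(bh_adjust([0.001], m=100), [0.1])

    def test_m_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)


class TestBuildEdges:
    def _score_frames(self, mat, taxa):
        df = pd.DataFrame(mat, index=taxa, columns=taxa)
        return {m: df.copy() for m in ("pearson", "spearman", "bray_curtis", "kld")}

    def test_all_insignificant_gives_empty_edgelist(self):
        taxa = list("abc")
        scores = self._score_frames(np.full((3, 3), 0.9), taxa)
        pmats = self._score_frames(np.ones((3, 3)), taxa)
        cfg = AssociationConfig(seed=0)
        edges = build_edges(scores, pmats, cfg)
        assert len(edges) == 0
        assert list(edges.columns)[:4] == ["taxon_a", "taxon_b", "sign", "ensemble_score"]

    def test_sign_conflicts_are_dropped_and_logged(self, caplog):
        taxa = list("ab")
        scores = self._score_frames(np.array([[1.0, 0.9], [0.9, 1.0]]), taxa)
        scores["spearman"] *= -1
        pmats = self._score_frames(np.full((2, 2), 1e-6), taxa)
        with caplog.at_level(logging.INFO, logger="cooccurnet.association"):
            edges = build_edges(scores, pmats, AssociationConfig(seed=0))
        assert len(edges) == 0
        assert any("conflicting" in r.message for r in caplog.records)

    def test_canonical_ordering_no_self_or_duplicate_edges(self, planted):
        edges = planted["edges"]
        assert (edges["taxon_a"] < edges["taxon_b"]).all()
        pairs = list(zip(edges["taxon_a"], edges["taxon_b"]))
        assert len(pairs) == len(set(pairs))

    def test_raising_score_threshold_never_adds_edges(self, planted):
        table = planted["table"].iloc[:40]
        cfg_lo = AssociationConfig(seed=5, n_permutations=300, score_threshold=0.6)
        cfg_hi = AssociationConfig(seed=5, n_permutations=300, score_threshold=0.8)
        scores, _ = pairwise_scores(table, cfg_lo)
        pmats = {
            m: permutation_pvalues(table, m, n_permutations=300, seed=5)
            for m in cfg_lo.measures
        }
        lo = build_edges(scores, pmats, cfg_lo)
        hi = build_edges(scores, pmats, cfg_hi)
        lo_pairs = set(zip(lo["taxon_a"], lo["taxon_b"]))
        hi_pairs = set(zip(hi["taxon_a"], hi["taxon_b"]))
        assert hi_pairs <= lo_pairs


class TestEnsembleNetwork:
    def test_planted_edges_recovered_with_high_precision(self, planted):
        edges, truth = planted["edges"], planted["truth"]
        assert len(edges) > 30
        true_pairs = {frozenset((a, b)) for a, b, _ in truth.true_edges}
        hits = sum(
            frozenset((r.taxon_a, r.taxon_b)) in true_pairs for r in edges.itertuples()
        )
        assert hits / len(edges) >= 0.9

    def test_competitive_keystone_edges_are_negative(self, planted):
        edges, truth = planted["edges"], planted["truth"]
        key_edges = edges[
            edges["taxon_a"].isin(truth.keystone_ids)
            | edges["taxon_b"].isin(truth.keystone_ids)
        ]
        assert len(key_edges) > 0
        assert (key_edges["sign"] == -1).all()

    def test_edge_qvalues_below_alpha(self, planted):
        assert (planted["edges"]["q"] < 0.01).all()
        assert (planted["edges"]["merged_p"] <= planted["edges"]["q"] + 1e-15).all()


def test_filter_prevalent_keeps_only_ubiquitous_taxa():
    t = _table([[1, 2, 3, 4], [0, 2, 3, 4], [5, 5, 0, 5]])
    out = filter_prevalent(t)
    assert list(out.index) == ["t0"]
    half = filter_prevalent(t, min_prevalence=0.75)
    assert list(half.index) == ["t0", "t1", "t2"]


def test_relative_abundance_columns_sum_to_one(rng):
    t = _table(rng.integers(1, 50, size=(6, 5)))
    np.testing.assert_allclose(relative_abundance(t).sum(0), 1.0)
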