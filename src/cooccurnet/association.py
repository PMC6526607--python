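"""Ensemble pairwise association inference for OTU tables.

Implements a CoNet-style ensemble: four association measures between taxon
abundance profiles (Pearson and Spearman correlation, Bray-Curtis
similarity, and a Kullback-Leibler similarity), per-measure permutation
p-values, Brown's method to merge the four dependent p-values per taxon
pair, and Benjamini-Hochberg FDR control over the candidate pairs.  The
result is a signed, significance-annotated edge list.

Semantics
---------
* Correlations are computed on relative abundances and are signed scores
  in [-1, 1].
* Bray-Curtis similarity is ``1 - dissimilarity`` in [0, 1].
* KLD similarity is ``exp(-symmetrized KL)`` in (0, 1], computed on
  pseudocounted, per-taxon renormalized abundance profiles; symmetrized
  KL is ``(KL(p||q) + KL(q||p)) / 2``.
* The permutation null shuffles each taxon's values across samples
  independently, destroying between-taxon dependence while preserving
  marginals.  Empirical p-values carry the +1/(n+1) correction so they
  are never zero (Brown's method takes logs).
* A pair is a *candidate* when at least ``min_support`` measures pass
  ``score_threshold`` and Pearson and Spearman agree in sign; the
  multiple-testing universe is the candidate set.  An edge is kept when
  its BH-adjusted merged p-value falls below ``alpha``; its sign is the
  sign of the mean of the two correlation scores (the unsigned similarity
  measures contribute evidence, never sign).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import ndtr
from scipy.stats import chi2, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationConfig",
    "MEASURES",
    "relative_abundance",
    "filter_prevalent",
    "pairwise_scores",
    "permutation_pvalues",
    "browns_merge",
    "covariance_from_nulls",
    "estimate_measure_covariance",
    "bh_adjust",
    "build_edges",
    "ensemble_network",
]

MEASURES = ("pearson", "spearman", "bray_curtis", "kld")
_SIMILARITY = frozenset({"bray_curtis", "kld"})
_TOL = 1e-12


@dataclass(frozen=True)
class AssociationConfig:
    """Tunables of the ensemble pipeline (defaults follow the study design:
    score threshold 0.7, alpha 0.01, 1000 permutations)."""

    measures: tuple[str, ...] = MEASURES
    score_threshold: float = 0.7
    n_permutations: int = 1000
    alpha: float = 0.01
    min_support: int = 2
    pseudocount: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.measures) - set(MEASURES)
        if not self.measures or unknown:
            raise ValueError(f"measures must be a non-empty subset of {MEASURES}; got {unknown}")
        if not 0 < self.score_threshold < 1:
            raise ValueError("score_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.min_support <= len(self.measures):
            raise ValueError("min_support must be in [1, n_measures]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize counts to per-sample relative abundances."""
    sums = table.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("cannot normalize all-zero sample(s)")
    return table / sums


def filter_prevalent(table: pd.DataFrame, min_prevalence: float = 1.0) -> pd.DataFrame:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of
    samples; the default keeps only taxa present in every sample of the
    group, the prevalence rule applied before network construction."""
    frac = (table > 0).mean(axis=1)
    return table.loc[frac >= min_prevalence]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / safe
    z[(sd == 0).ravel()] = 0.0
    return z


class _Engine:
    """Precomputed transformed inputs; scores under identity or a
    row-wise permutation (same permutation applied to every measure)."""

    def __init__(self, rel: np.ndarray, measures: Sequence[str], pseudocount: float):
        self.measures = tuple(measures)
        self.n, self.s = rel.shape
        self.zero_var = rel.std(axis=1) == 0
        self.inputs: dict[str, tuple[np.ndarray, ...]] = {}
        if "pearson" in measures:
            self.inputs["pearson"] = (_standardize_rows(rel),)
        if "spearman" in measures:
            self.inputs["spearman"] = (_standardize_rows(rankdata(rel, axis=1)),)
        if "bray_curtis" in measures:
            rs = rel.sum(axis=1)
            denom = rs[:, None] + rs[None, :]
            self.inputs["bray_curtis"] = (rel, np.where(denom > 0, denom, np.inf))
        if "kld" in measures:
            p = rel + pseudocount
            p = p / p.sum(axis=1, keepdims=True)
            self.inputs["kld"] = (p, np.log(p))

    def _permute(self, arr: np.ndarray, idx: np.ndarray | None) -> np.ndarray:
        return arr if idx is None else np.take_along_axis(arr, idx, axis=1)

    def scores(self, idx: np.ndarray | None = None) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for m in self.measures:
            if m in ("pearson", "spearman"):
                z = self._permute(self.inputs[m][0], idx)
                out[m] = np.clip(z @ z.T / self.s, -1.0, 1.0)
            elif m == "bray_curtis":
                x, denom = self.inputs[m]
                xp = self._permute(x, idx)
                out[m] = 1.0 - cdist(xp, xp, metric="cityblock") / denom
            else:  # kld
                p, logp = self.inputs[m]
                pp = self._permute(p, idx)
                lp = self._permute(logp, idx)
                mpl = pp @ lp.T
                e = np.diag(mpl)
                d = 0.5 * (e[:, None] + e[None, :] - mpl - mpl.T)
                out[m] = np.exp(-np.clip(d, 0.0, None))
        return out


def pairwise_scores(
    table: pd.DataFrame, config: AssociationConfig = AssociationConfig()
) -> tuple[dict[str, pd.DataFrame], list]:
    """Observed per-measure taxon x taxon score matrices.

    Returns the score matrices plus the list of zero-variance taxa, whose
    correlation scores are set to 0 (flagged, not an exception).
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    rel = relative_abundance(table).to_numpy(dtype=float)
    eng = _Engine(rel, config.measures, config.pseudocount)
    raw = eng.scores()
    scores = {
        m: pd.DataFrame(raw[m], index=table.index, columns=table.index) for m in config.measures
    }
    flagged = list(table.index[eng.zero_var])
    return scores, flagged


def _run_permutations(
    eng: _Engine,
    n_permutations: int,
    seed,
    pool: np.ndarray | None = None,
    tail_extension: bool = False,
):
    """Shared permutation loop: observed scores, exceedance counts, and
    (optionally) the null scores of a pool of pairs for covariance
    estimation.  One permutation replicate applies an independent
    within-row shuffle, shared across measures.

    With ``tail_extension`` the unresolvable region of the empirical p
    (fewer than 10 null exceedances) is extended by a Gaussian tail
    fitted to the per-pair null moments, so that very strong
    associations are not all collapsed onto the 1/(N+1) floor.
    """
    rng = np.random.default_rng(seed)
    obs = eng.scores()
    absobs = {m: np.abs(v) for m, v in obs.items()}
    cnt = {m: np.zeros((eng.n, eng.n), dtype=np.int64) for m in eng.measures}
    cnt_lo = {m: np.zeros((eng.n, eng.n), dtype=np.int64) for m in eng.measures if m in _SIMILARITY}
    if tail_extension:
        s1 = {m: np.zeros((eng.n, eng.n)) for m in eng.measures}
        s2 = {m: np.zeros((eng.n, eng.n)) for m in eng.measures}
    nulls = (
        {m: np.empty((n_permutations, pool.shape[0])) for m in eng.measures}
        if pool is not None
        else None
    )
    base = np.tile(np.arange(eng.s), (eng.n, 1))
    for r in range(n_permutations):
        idx = rng.permuted(base, axis=1)
        null = eng.scores(idx)
        for m in eng.measures:
            if m in _SIMILARITY:
                cnt[m] += null[m] + _TOL >= obs[m]
                cnt_lo[m] += null[m] - _TOL <= obs[m]
            else:
                cnt[m] += np.abs(null[m]) + _TOL >= absobs[m]
            if tail_extension:
                s1[m] += null[m]
                s2[m] += null[m] ** 2
            if nulls is not None:
                nulls[m][r] = null[m][pool[:, 0], pool[:, 1]]
    pvals = {}
    for m in eng.measures:
        if m in _SIMILARITY:
            # two-sided for non-negative similarity scores: double the
            # smaller tail (co-presence high, mutual exclusion low)
            hi = (1.0 + cnt[m]) / (1.0 + n_permutations)
            lo = (1.0 + cnt_lo[m]) / (1.0 + n_permutations)
            p = np.minimum(1.0, 2.0 * np.minimum(hi, lo))
            resolvable = np.minimum(cnt[m], cnt_lo[m]) >= 10
        else:
            p = (1.0 + cnt[m]) / (1.0 + n_permutations)
            resolvable = cnt[m] >= 10
        if tail_extension:
            mu = s1[m] / n_permutations
            var = np.clip(s2[m] / n_permutations - mu**2, 0.0, None)
            sd = np.sqrt(var)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.abs(obs[m] - mu) / sd
            p_gauss = np.where(sd > 0, 2.0 * ndtr(-z), 1.0)
            p = np.where(resolvable, p, np.minimum(p, np.clip(p_gauss, 1e-12, None)))
        np.fill_diagonal(p, 1.0)
        pvals[m] = p
    return obs, pvals, nulls


def permutation_pvalues(
    table: pd.DataFrame, measure: str, n_permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Two-sided empirical permutation p-values for one measure.

    For the signed correlations, p = (1 + #{|null| >= |observed|}) /
    (1 + n_permutations).  For the non-negative similarities, where the
    absolute value cannot express two-sidedness, the smaller tail is
    doubled: p = min(1, 2 * min(hi, lo)) with hi/lo the (+1-corrected)
    upper/lower tail frequencies — low similarity (mutual exclusion) is
    as extreme as high similarity (co-presence).

    Constant (zero-variance) taxa score 0 against everything under both
    the observed and null statistics, so their p-values are 1.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    rel = relative_abundance(table).to_numpy(dtype=float)
    eng = _Engine(rel, (measure,), AssociationConfig().pseudocount)
    _, pvals, _ = _run_permutations(eng, n_permutations, seed)
    return pd.DataFrame(pvals[measure], index=table.index, columns=table.index)


def browns_merge(p_values, covariance) -> float:
    """Combine dependent p-values with Brown's scaled chi-square method.

    psi = -2 sum ln p has null mean E = 2k and variance
    Var = 4k + 2 sum_{i<j} cov_ij where cov_ij = cov(-2 ln p_i, -2 ln p_j);
    the merged p-value is the upper tail of chi^2_f at psi/c with
    c = Var/(2E), f = 2E^2/Var.  With zero covariance this is exactly
    Fisher's method.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape != (len(p), len(p)):
        raise ValueError("covariance must be k x k")
    if not np.allclose(cov, cov.T) or np.linalg.eigvalsh(cov).min() < -1e-8:
        raise ValueError("covariance must be symmetric positive semi-definite")
    if len(p) == 1:
        return float(p[0])
    return float(_browns_merge_many(p[None, :], cov)[0])


def _browns_merge_many(p: np.ndarray, cov: np.ndarray) -> np.ndarray:
    k = p.shape[1]
    psi = -2.0 * np.log(p).sum(axis=1)
    expected = 2.0 * k
    var = 4.0 * k + 2.0 * cov[np.triu_indices(k, 1)].sum()
    var = max(var, 1e-12)
    c = var / (2.0 * expected)
    f = 2.0 * expected**2 / var
    return chi2.sf(psi / c, f)


def covariance_from_nulls(nulls: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Covariance of the -2 ln p statistics across measures.

    ``nulls[m]`` holds null scores with shape (n_replicates, n_pairs);
    each replicate's p-value is its within-null exceedance rank (so the
    p's are uniform on {1/R, ..., 1} by construction), and the covariance
    is pooled over pairs.  The result is clipped to the nearest PSD
    matrix.  For a single measure the diagonal is ~4, the variance of a
    chi-square(2) variate.
    """
    measures = list(nulls)
    mats = [np.asarray(nulls[m], dtype=float) for m in measures]
    n_rep = mats[0].shape[0]
    if n_rep < 100:
        raise ValueError("need at least 100 null replicates")
    if any(v.shape != mats[0].shape for v in mats):
        raise ValueError("null score arrays must share a shape")
    xs = []
    for m, v in zip(measures, mats):
        if m in _SIMILARITY:
            hi = rankdata(-v, axis=0, method="max") / n_rep
            lo = rankdata(v, axis=0, method="max") / n_rep
            pr = np.minimum(1.0, 2.0 * np.minimum(hi, lo))
        else:
            pr = rankdata(-np.abs(v), axis=0, method="max") / n_rep
        xs.append(-2.0 * np.log(pr))
    x = np.stack(xs)  # (k, n_rep, n_pairs)
    xc = x - x.mean(axis=1, keepdims=True)
    cov = np.einsum("mrp,nrp->mn", xc, xc) / ((n_rep - 1) * x.shape[2])
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    return pd.DataFrame(cov, index=measures, columns=measures)


def estimate_measure_covariance(
    table: pd.DataFrame,
    config: AssociationConfig = AssociationConfig(),
    n_pool: int = 200,
) -> pd.DataFrame:
    """Estimate the Brown covariance for ``config.measures`` from the
    permutation null of ``table``, pooled over a seeded random subsample
    of at most ``n_pool`` taxon pairs."""
    if config.n_permutations < 100:
        raise ValueError("need at least 100 null replicates")
    rel = relative_abundance(table).to_numpy(dtype=float)
    eng = _Engine(rel, config.measures, config.pseudocount)
    pool = _pair_pool(eng.n, n_pool, np.random.default_rng([config.seed, 1]))
    _, _, nulls = _run_permutations(eng, config.n_permutations, [config.seed, 0], pool)
    return covariance_from_nulls(nulls)


def _pair_pool(n: int, n_pool: int, rng) -> np.ndarray:
    iu = np.column_stack(np.triu_indices(n, 1))
    if len(iu) <= n_pool:
        return iu
    return iu[rng.choice(len(iu), size=n_pool, replace=False)]


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m/j,
    capped at 1, returned in the input order.  ``m`` defaults to the
    number of tests and may be larger (partial universes)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("m must be at least len(p_values)")
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def build_edges(
    scores: Mapping[str, pd.DataFrame],
    p_matrices: Mapping[str, pd.DataFrame],
    config: AssociationConfig = AssociationConfig(),
    covariance=None,
) -> pd.DataFrame:
    """Assemble the significant edge list from score and p-value matrices.

    Candidates need >= ``min_support`` measures at ``score_threshold``
    (absolute value for correlations) and sign agreement between Pearson
    and Spearman; merged p-values come from Brown's method (Fisher when
    ``covariance`` is None), q-values from BH over the candidates, and
    edges with q < ``alpha`` are kept.  Pairs meeting support but with
    conflicting correlation signs are dropped and logged.
    """
    measures = config.measures
    taxa = scores[measures[0]].index
    n = len(taxa)
    iu = np.triu_indices(n, 1)
    svec = {m: scores[m].to_numpy(dtype=float)[iu] for m in measures}
    pvec = {m: np.asarray(p_matrices[m], dtype=float)[iu] for m in measures}

    corr = [m for m in ("pearson", "spearman") if m in measures]
    # Candidacy is driven by the signed correlation measures (the
    # similarity scores saturate for unexceptional pairs and would
    # otherwise swamp the multiplicity universe); similarities still
    # contribute evidence through the merged p-value.  Configs without a
    # correlation measure fall back to counting every configured measure.
    support_measures = corr if corr else list(measures)
    support = np.zeros(len(iu[0]), dtype=int)
    for m in support_measures:
        passed = (svec[m] >= config.score_threshold) if m in _SIMILARITY else (
            np.abs(svec[m]) >= config.score_threshold
        )
        support += passed
    if len(corr) == 2:
        agree = svec["pearson"] * svec["spearman"] >= 0
    else:
        agree = np.ones(len(iu[0]), dtype=bool)
    cand = (support >= config.min_support) & agree
    n_dropped = int(((support >= config.min_support) & ~agree).sum())
    if n_dropped:
        logger.info("dropped %d pair(s) with conflicting correlation signs", n_dropped)

    cols = {
        "taxon_a": np.asarray(taxa)[iu[0]][cand],
        "taxon_b": np.asarray(taxa)[iu[1]][cand],
    }
    if not cand.any():
        empty = pd.DataFrame(
            columns=["taxon_a", "taxon_b", "sign", "ensemble_score", *measures, "merged_p", "q"]
        )
        logger.info("candidates=0 kept=0")
        return empty

    pmat = np.column_stack([pvec[m][cand] for m in measures])
    if covariance is None:
        cov = np.zeros((len(measures), len(measures)))
    else:
        cov = (
            covariance.loc[list(measures), list(measures)].to_numpy()
            if isinstance(covariance, pd.DataFrame)
            else np.asarray(covariance, dtype=float)
        )
    merged = _browns_merge_many(pmat, cov)
    # BH over the candidate p-values with m = every pair tested: the score
    # filter *selects* small permutation p-values, so correcting only
    # within the survivors would keep chance-extreme pairs under the null
    q = bh_adjust(merged, m=len(iu[0]))

    if corr:
        mean_corr = np.mean([svec[m][cand] for m in corr], axis=0)
        sign = np.where(mean_corr >= 0, 1, -1)
    else:
        sign = np.ones(cand.sum(), dtype=int)
    ensemble = np.mean([np.abs(svec[m][cand]) for m in measures], axis=0)

    frame = pd.DataFrame(
        {
            **cols,
            "sign": sign,
            "ensemble_score": ensemble,
            **{m: svec[m][cand] for m in measures},
            "merged_p": merged,
            "q": q,
        }
    )
    # canonical ordering taxon_a < taxon_b
    flip = frame["taxon_a"] > frame["taxon_b"]
    if flip.any():
        a = frame.loc[flip, "taxon_b"].copy()
        frame.loc[flip, "taxon_b"] = frame.loc[flip, "taxon_a"]
        frame.loc[flip, "taxon_a"] = a
    kept = frame[frame["q"] < config.alpha].sort_values(
        ["q", "taxon_a", "taxon_b"], kind="stable"
    )
    logger.info(
        "threshold=%.2f alpha=%.3g seed=%s candidates=%d kept=%d",
        config.score_threshold,
        config.alpha,
        config.seed,
        int(cand.sum()),
        len(kept),
    )
    return kept.reset_index(drop=True)


def ensemble_network(
    table: pd.DataFrame,
    config: AssociationConfig = AssociationConfig(),
    n_pool: int = 200,
) -> pd.DataFrame:
    """End-to-end ensemble inference on one group's OTU table.

    Runs one shared permutation pass for all configured measures (scores,
    p-values, and the null pool for the Brown covariance), then filters,
    merges, and FDR-adjusts via :func:`build_edges`.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    rel = relative_abundance(table).to_numpy(dtype=float)
    eng = _Engine(rel, config.measures, config.pseudocount)
    pool = _pair_pool(eng.n, n_pool, np.random.default_rng([config.seed, 1]))
    obs, pvals, nulls = _run_permutations(
        eng, config.n_permutations, [config.seed, 0], pool, tail_extension=True
    )
    cov = covariance_from_nulls(nulls) if config.n_permutations >= 100 else None
    scores = {m: pd.DataFrame(obs[m], index=table.index, columns=table.index) for m in config.measures}
    pmats = {m: pd.DataFrame(pvals[m], index=table.index, columns=table.index) for m in config.measures}
    return build_edges(scores, pmats, config, covariance=cov)
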