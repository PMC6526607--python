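"""Module eigengenes and module/keystone-trait correlation analysis.

A module eigengene is the first principal component of the standardized
(member x sample) abundance matrix — one representative per-sample
profile per module, computed here by SVD on relative abundances.  The
eigengene's sign is fixed by aligning it with the member-average
standardized profile, which makes downstream trait-correlation signs
reproducible.  Trait relationships use Spearman rank correlation with a
t-approximation p-value for n >= 10 and an exact permutation p-value for
smaller n, BH-adjusted per correlation table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = [
    "ModuleEigengene",
    "module_eigengene",
    "spearman_test",
    "trait_correlations",
    "export_downstream",
]

_EXACT_N = 10  # below this, Spearman p is an exact permutation test


@dataclass
class ModuleEigengene:
    module: object
    eigengene: pd.Series  # unit-norm, one value per sample
    variance_explained: float
    members: tuple


def module_eigengene(table: pd.DataFrame, members, module=None) -> ModuleEigengene:
    """First principal component of a module's standardized profiles.

    Member rows are standardized to mean 0, sd 1 across samples;
    zero-variance members are excluded with a warning; fewer than two
    usable members is an error.  ``variance_explained`` is
    s1^2 / sum(s_i^2) of the singular values.
    """
    members = [m for m in members]
    missing = [m for m in members if m not in table.index]
    if missing:
        raise ValueError(f"member(s) not in table: {missing[:5]}")
    x = table.loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [m for m, s in zip(members, sd) if s == 0]
        warnings.warn(f"excluding zero-variance member(s): {bad}", stacklevel=2)
        members = [m for m, s in zip(members, sd) if s > 0]
        x = table.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1)
    if len(members) < 2:
        raise ValueError("need at least 2 members with nonzero variance")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    align = float(eig @ mean_profile)
    if abs(align) < 1e-12:
        nz = np.flatnonzero(np.abs(eig) > 1e-12)  # degenerate tie: fix by first element
        if len(nz) and eig[nz[0]] < 0:
            eig = -eig
    elif align < 0:
        eig = -eig
    return ModuleEigengene(
        module=module,
        eigengene=pd.Series(eig, index=table.columns),
        variance_explained=float(s[0] ** 2 / (s**2).sum()),
        members=tuple(members),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all n! pairings of the rank vectors; ties are handled by
    computing Pearson correlation on (possibly midranked) ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    obs = abs(rx @ ry / n)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx[perms] @ ry) / n
    return float((np.abs(rhos) >= obs - 1e-12).sum() / math.factorial(n))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p (t-approximation for n >= 10, exact
    permutation below)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if len(x) < _EXACT_N:
        p = _exact_spearman_p(x, y)
    return float(rho), float(p)


def trait_correlations(vectors: Mapping, traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each vector (module eigengene or keystone
    abundance profile) against each trait.

    Vectors and traits are aligned by sample id; incomplete pairs are
    dropped per correlation.  Constant vectors/traits yield a flagged row
    with rho = NaN, excluded from the BH universe; ``q`` is BH-adjusted
    across the whole table.
    """
    rows = []
    for vid, vec in vectors.items():
        v = pd.Series(vec).astype(float)
        for trait in traits.columns:
            t = traits[trait].astype(float)
            common = v.index.intersection(t.index)
            paired = pd.DataFrame({"v": v.reindex(common), "t": t.reindex(common)}).dropna()
            if len(paired) < 4:
                raise ValueError(
                    f"fewer than 4 paired observations for ({vid!r}, {trait!r})"
                )
            rho, p = spearman_test(paired["v"], paired["t"])
            rows.append((vid, trait, rho, p, len(paired), np.isnan(rho)))
    out = pd.DataFrame(
        rows, columns=["id", "trait", "spearman_rho", "p", "n", "degenerate"]
    )
    out["q"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def export_downstream(
    traits: pd.DataFrame,
    eigengenes: Mapping,
    diversity: pd.DataFrame | None = None,
    feature_traits: tuple = ("smc", "ph"),
    target_traits: tuple = ("carbohydrate_util", "qco2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis-ready tables for downstream model fitting.

    Returns (features, targets): one samples x features table (soil
    traits, diversity, module eigengenes as ``ME_<id>``) and one table of
    the functional response traits.  Sample ids must agree everywhere.
    """
    samples = traits.index
    features = pd.DataFrame(index=samples)
    for c in feature_traits:
        if c in traits.columns:
            features[c] = traits[c]
    if diversity is not None:
        bad = sorted(set(samples).symmetric_difference(diversity.index))
        if bad:
            raise ValueError(f"sample-id mismatch with diversity table: {bad}")
        for c in diversity.columns:
            features[c] = diversity[c]
    for mid, me in eigengenes.items():
        vec = me.eigengene if isinstance(me, ModuleEigengene) else pd.Series(me)
        bad = sorted(set(samples).symmetric_difference(vec.index))
        if bad:
            raise ValueError(f"sample-id mismatch for eigengene {mid!r}: {bad}")
        features[f"ME_{mid}"] = vec.reindex(samples)
    targets = traits[[c for c in target_traits if c in traits.columns]].copy()
    return features, targets
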