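"""Diversity, ordination, and functional metrics for OTU tables.

Conventions: an OTU table is a pandas DataFrame of non-negative integer
counts with taxa as rows and samples as columns.  Shannon uses natural
log by default; Chao1 is bias-corrected by default so doubleton-free
samples are well defined.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "awcd",
    "metabolic_quotient",
]


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample (column) to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw); single draw per sample,
    reproducible from ``seed``."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sum(axis=0)
    short = sums[sums < depth]
    if len(short):
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total count of sample(s) "
            f"{', '.join(map(str, short.index))}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    counts = table.to_numpy(dtype=np.int64)
    for j in range(table.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def alpha_diversity(
    table: pd.DataFrame, base: float | None = None, bias_corrected: bool = True
) -> pd.DataFrame:
    """Per-sample Shannon H', Chao1, and observed richness.

    H' = -sum p_i log p_i over nonzero relative abundances (natural log
    unless ``base`` is given).  Bias-corrected Chao1 =
    S_obs + F1(F1-1)/(2(F2+1)); the classical form S_obs + F1^2/(2 F2)
    is used when ``bias_corrected=False`` (falling back to the corrected
    form when F2 = 0, where the classical estimator is undefined).
    """
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if len(dead):
        raise ValueError(
            f"sample(s) {', '.join(str(table.columns[j]) for j in dead)} have zero total count"
        )
    rows = []
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    for j, sample in enumerate(table.columns):
        c = counts[:, j]
        nz = c[c > 0]
        p = nz / nz.sum()
        shannon = float(-(p * log(p)).sum())
        s_obs = len(nz)
        f1 = int((nz == 1).sum())
        f2 = int((nz == 2).sum())
        if bias_corrected or f2 == 0:
            chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        else:
            chao1 = s_obs + f1 * f1 / (2.0 * f2)
        rows.append((sample, shannon, chao1, s_obs))
    return pd.DataFrame(
        rows, columns=["sample", "shannon", "chao1", "observed_richness"]
    ).set_index("sample")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples,
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(dtype=float).T
    zero = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero) >= 2:
        raise ValueError(
            "Bray-Curtis undefined between all-zero samples: "
            + ", ".join(str(table.columns[j]) for j in zero)
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def pcoa(d: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (principal coordinate analysis).

    Double-centers -0.5 d^2, eigendecomposes, and returns the top-``k``
    coordinates scaled by sqrt(eigenvalue).  The full eigenvalue spectrum
    is returned in descending order, negative values included; axes with
    non-positive eigenvalues get zero coordinates.
    """
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not (k >= 1 and k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = np.sqrt(np.clip(eigval[:k], 0.0, None))
    coords = eigvec[:, :k] * scale
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=d.index, columns=cols), eigval


def awcd(
    plate: pd.DataFrame,
    blank,
    t,
    family_of: Mapping,
) -> tuple[float, pd.Series]:
    """Average well color development from a 31-substrate plate read.

    ``plate`` is wells x timepoints OD590; ``blank`` the control-well OD
    per timepoint (Series/dict aligned to columns, or a scalar).  Each
    well's value at timepoint ``t`` is max(OD_well - OD_blank, 0); AWCD is
    the mean over the 31 substrate wells and ``family_of`` groups wells
    into the six substrate families for per-family means.
    """
    if plate.shape[0] != 31:
        raise ValueError(f"expected 31 substrate wells, got {plate.shape[0]}")
    if t not in plate.columns:
        raise ValueError(f"timepoint {t!r} not present in plate columns")
    if np.isscalar(blank):
        b = float(blank)
    else:
        b = pd.Series(blank)[t]
    vals = (plate[t] - b).clip(lower=0.0)
    fams = pd.Series({w: family_of[w] for w in plate.index})
    family_means = vals.groupby(fams).mean()
    return float(vals.mean()), family_means


def metabolic_quotient(basal_respiration: float, microbial_biomass: float) -> float:
    """qCO2: basal respiration per unit microbial biomass."""
    if microbial_biomass <= 0:
        raise ValueError("microbial_biomass must be positive")
    if basal_respiration < 0:
        raise ValueError("basal_respiration must be non-negative")
    return basal_respiration / microbial_biomass
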