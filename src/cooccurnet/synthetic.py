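"""Synthetic microbial community generator with planted network structure.

Emulates the statistical structure of a rarefied amplicon survey of a
two-condition soil experiment: a taxa x samples integer count table whose
taxa are organized into latent "modules" (groups of co-varying taxa), a
trait table statistically coupled to module activity, and a set of
substrate-labeled taxa (the in-silico analogue of a DNA-SIP incubation).
Every generated dataset carries its ground truth, so downstream network
inference can be scored for edge precision, module recovery, and keystone
identification.

Generative model
----------------
Per module ``m`` and sample ``j`` a latent activity ``a_mj ~ N(0, latent_sd)``
is drawn.  A taxon ``i`` belonging to module ``m`` has log relative
abundance::

    log w_ij = base_i + lambda_i * a_mj + eps_ij

with per-taxon loading ``lambda_i`` drawn uniformly from ``loading_range``
and intrinsic noise ``eps_ij ~ N(0, sd_i)``.  Background taxa omit the
latent term.  Relative abundances are the softmax of ``log w`` within each
sample, and counts are multinomial draws at ``sequencing_depth`` — a
compositional count model mirroring a rarefied OTU table.  ``dispersion``
sets the intrinsic-noise scale ``sd_i`` and thereby the count
overdispersion.

Keystones are planted hubs: the first ``keystone_per_module`` taxa of each
module receive the maximal (unit) loading, above the member
``loading_range``, with sign ``keystone_sign`` (``-1`` = competitive:
abundance moves against the module), and intrinsic noise shrunk by
``keystone_noise_factor`` so they track their module's activity more
tightly than ordinary members.  That asymmetry is what makes a planted
keystone a *hub* — its associations with every member are systematically
stronger than member-member associations — rather than an exchangeable
member with a flipped sign.

A two-condition experiment is built from two designs that differ only in
``keystone_sign`` (+1 cooperative vs -1 competitive) and seed; each
condition is analyzed as its own network.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityDesign",
    "DesignError",
    "SyntheticTruth",
    "generate_counts",
    "generate_traits",
    "generate_sip_labels",
    "write_truth",
]


class DesignError(ValueError):
    """Raised when a CommunityDesign is internally inconsistent."""


# independent child-stream keys; all randomness flows from design.seed
_COUNT_STREAM = 0
_TRAIT_STREAM = 1
_LABEL_STREAM = 2


@dataclass(frozen=True)
class CommunityDesign:
    """Parameters of the synthetic community.

    Parameters
    ----------
    n_samples_per_group:
        Replicate block size; one call to :func:`generate_counts` yields
        ``2 * n_samples_per_group`` samples under a single condition.
    n_taxa:
        Total taxa; taxa not claimed by ``module_sizes`` are independent
        background taxa.
    module_sizes:
        Size of each planted module (each >= 3).
    latent_sd:
        Scale of the per-module latent activity (log-abundance units).
    loading_range:
        Interval in (0, 1] from which member loadings are drawn.
    keystone_per_module:
        Planted hubs per module; they take unit loading (above the member
        range) with sign ``keystone_sign``.
    keystone_sign:
        +1 cooperative or -1 competitive keystone coupling.
    keystone_noise_factor:
        Multiplier (<= 1) on ``dispersion`` for keystone intrinsic noise.
    dispersion:
        Standard deviation of the intrinsic log-abundance noise.
    sequencing_depth:
        Multinomial total per sample (>= n_taxa).
    trait_model:
        Mapping trait name -> (module index, coefficient, noise sd).
    labeled_fraction:
        Fraction of taxa marked substrate-labeled (keystones always are).
    seed:
        Sole source of randomness; two calls with equal designs are
        bit-identical.
    """

    n_samples_per_group: int = 15
    n_taxa: int = 120
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (10, 10, 10)
    latent_sd: float = 0.45
    loading_range: tuple[float, float] = (0.55, 0.8)
    keystone_per_module: int = 1
    keystone_sign: int = -1
    keystone_noise_factor: float = 0.25
    dispersion: float = 0.1
    sequencing_depth: int = 20_000
    trait_model: Mapping[str, tuple[int, float, float]] = field(default_factory=dict)
    labeled_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_taxa < 1:
            raise DesignError("n_samples_per_group and n_taxa must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise DesignError(
                f"n_modules={self.n_modules} but {len(self.module_sizes)} module_sizes given"
            )
        if any(s < 3 for s in self.module_sizes):
            raise DesignError("every module must have at least 3 taxa")
        if sum(self.module_sizes) > self.n_taxa:
            raise DesignError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_taxa={self.n_taxa}"
            )
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise DesignError("loading_range must lie within (0, 1]")
        if self.latent_sd <= 0 or self.dispersion <= 0:
            raise DesignError("latent_sd and dispersion must be positive")
        if not 0 < self.keystone_noise_factor <= 1:
            raise DesignError("keystone_noise_factor must be in (0, 1]")
        if self.keystone_sign not in (-1, 1):
            raise DesignError("keystone_sign must be +1 or -1")
        if self.keystone_per_module < 0:
            raise DesignError("keystone_per_module must be non-negative")
        if self.module_sizes and self.keystone_per_module > min(self.module_sizes):
            raise DesignError("keystone_per_module exceeds the smallest module")
        if self.sequencing_depth < self.n_taxa:
            raise DesignError("sequencing_depth must be >= n_taxa")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise DesignError("labeled_fraction must be in [0, 1]")
        for name, (m, _, sd) in dict(self.trait_model).items():
            if not 0 <= m < self.n_modules:
                raise DesignError(f"trait {name!r} references unknown module {m}")
            if sd < 0:
                raise DesignError(f"trait {name!r} has negative noise sd")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    def replace(self, **changes) -> "CommunityDesign":
        return dataclasses.replace(self, **changes)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``module_of`` maps taxon id -> module index (-1 = background);
    ``latent_activity`` is modules x samples; ``true_edges`` holds
    canonical ``(a, b, sign)`` triples for every within-module pair, the
    sign being the product of the two loadings' signs; ``trait_values`` is
    the noise-free trait x sample matrix.
    """

    module_of: dict[str, int]
    latent_activity: pd.DataFrame
    keystone_ids: frozenset[str]
    true_edges: set[tuple[str, str, int]]
    labeled_taxa: frozenset[str]
    trait_values: pd.DataFrame
    loadings: pd.Series

    @property
    def taxa(self) -> list[str]:
        return list(self.module_of)

    def members_of(self, module: int) -> list[str]:
        return [t for t, m in self.module_of.items() if m == module]


def _taxon_ids(n: int) -> list[str]:
    return [f"OTU{i + 1:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{j + 1:03d}" for j in range(n)]


def generate_counts(design: CommunityDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one count table plus its ground truth.

    Returns
    -------
    table:
        ``n_taxa x (2 * n_samples_per_group)`` integer DataFrame whose
        columns each sum to ``sequencing_depth``.
    truth:
        :class:`SyntheticTruth` for the same draw (labeled taxa included,
        identical to what :func:`generate_sip_labels` returns).
    """
    rng = np.random.default_rng([design.seed, _COUNT_STREAM])
    n, s = design.n_taxa, design.n_samples
    taxa = _taxon_ids(n)
    samples = _sample_ids(s)

    module_of = np.full(n, -1, dtype=int)
    start = 0
    keystone_mask = np.zeros(n, dtype=bool)
    for m, size in enumerate(design.module_sizes):
        module_of[start : start + size] = m
        keystone_mask[start : start + design.keystone_per_module] = True
        start += size

    lo, hi = design.loading_range
    base = rng.normal(0.0, 1.0, size=n)
    loadings = rng.uniform(lo, hi, size=n)
    loadings[module_of < 0] = 0.0
    # keystones take the maximal coupling (unit loading), above the
    # member range, so the planted hub really is the best-connected node
    loadings[keystone_mask] = design.keystone_sign * 1.0

    activity = rng.normal(0.0, design.latent_sd, size=(design.n_modules, s))
    noise_sd = np.full(n, design.dispersion)
    noise_sd[keystone_mask] = design.dispersion * design.keystone_noise_factor
    eps = rng.normal(0.0, 1.0, size=(n, s)) * noise_sd[:, None]

    logw = base[:, None] + eps
    in_module = module_of >= 0
    if design.n_modules:
        logw[in_module] += loadings[in_module, None] * activity[module_of[in_module]]

    logw -= logw.max(axis=0, keepdims=True)  # softmax stability
    rel = np.exp(logw)
    rel /= rel.sum(axis=0, keepdims=True)

    counts = np.empty((n, s), dtype=np.int64)
    for j in range(s):
        counts[:, j] = rng.multinomial(design.sequencing_depth, rel[:, j])

    table = pd.DataFrame(counts, index=taxa, columns=samples)

    true_edges: set[tuple[str, str, int]] = set()
    for m in range(design.n_modules):
        members = np.flatnonzero(module_of == m)
        for ii, i in enumerate(members):
            for j in members[ii + 1 :]:
                sign = 1 if loadings[i] * loadings[j] > 0 else -1
                true_edges.add((taxa[i], taxa[j], sign))

    latent = pd.DataFrame(activity, index=range(design.n_modules), columns=samples)
    trait_truth = pd.DataFrame(
        {name: coef * latent.loc[m] for name, (m, coef, _) in dict(design.trait_model).items()}
    ).T
    if trait_truth.empty:
        trait_truth = pd.DataFrame(columns=samples)

    truth = SyntheticTruth(
        module_of=dict(zip(taxa, module_of.tolist())),
        latent_activity=latent,
        keystone_ids=frozenset(np.array(taxa)[keystone_mask].tolist()),
        true_edges=true_edges,
        labeled_taxa=frozenset(),
        trait_values=trait_truth,
        loadings=pd.Series(loadings, index=taxa),
    )
    truth.labeled_taxa = generate_sip_labels(truth, design)
    return table, truth


def generate_traits(truth: SyntheticTruth, design: CommunityDesign) -> pd.DataFrame:
    """Per-sample trait table coupled to module activities.

    Trait ``t`` for sample ``j`` is ``coef_t * a(m_t, j) + N(0, sd_t)``.
    Noise is keyed to sample ids (drawn in sorted-id order), so shuffling
    the sample order of ``truth.latent_activity`` leaves each sample's
    trait value unchanged.
    """
    rng = np.random.default_rng([design.seed, _TRAIT_STREAM])
    samples = list(truth.latent_activity.columns)
    order = sorted(samples)
    out = {}
    for name, (m, coef, sd) in dict(design.trait_model).items():
        if not 0 <= m < truth.latent_activity.shape[0]:
            raise DesignError(f"trait {name!r} references unknown module {m}")
        noise = pd.Series(rng.normal(0.0, 1.0, size=len(order)) * sd, index=order)
        out[name] = coef * truth.latent_activity.loc[m] + noise.reindex(samples)
    return pd.DataFrame(out, index=samples)


def generate_sip_labels(truth: SyntheticTruth, design: CommunityDesign) -> frozenset[str]:
    """Sample the substrate-labeled taxon set.

    ``round(labeled_fraction * n_taxa)`` taxa drawn without replacement,
    forced to contain every keystone (keystones are always recovered in
    the labeled heavy-DNA fraction); reproducible from the design seed.
    """
    rng = np.random.default_rng([design.seed, _LABEL_STREAM])
    taxa = truth.taxa
    n_lab = int(round(design.labeled_fraction * len(taxa)))
    keystones = sorted(truth.keystone_ids)
    if n_lab < len(keystones):
        raise DesignError(
            f"labeled_fraction={design.labeled_fraction} labels {n_lab} taxa, "
            f"fewer than the {len(keystones)} keystones"
        )
    others = [t for t in taxa if t not in truth.keystone_ids]
    extra = rng.choice(len(others), size=n_lab - len(keystones), replace=False)
    return frozenset(keystones + [others[i] for i in sorted(extra)])


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth as JSON (plain-text deliverable)."""
    payload = {
        "module_of": truth.module_of,
        "keystone_ids": sorted(truth.keystone_ids),
        "labeled_taxa": sorted(truth.labeled_taxa),
        "true_edges": sorted(list(e) for e in truth.true_edges),
        "latent_activity": {
            str(m): truth.latent_activity.loc[m].round(10).to_dict()
            for m in truth.latent_activity.index
        },
        "loadings": truth.loadings.round(10).to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
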