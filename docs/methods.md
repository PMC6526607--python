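# Methods

`cooccurnet` reimplements, as a tested pipeline, the network-analysis
chain used to link soil-microbiome keystone taxa to community diversity
and carbon-cycling function: ensemble co-occurrence inference on OTU
count tables, module detection, Zi–Pi node-role classification, module
eigengenes, and eigengene/keystone–trait correlation. Because the field
study it emulates deposited no sequence data, the pipeline ships a
synthetic-community generator with full ground truth; every recovery
claim the test suite makes is a claim about that generator's planted
structure, exercised through the same code paths a real OTU table would
take.

## Synthetic communities

**Model.** Each of `n_modules` modules has a latent per-sample activity
`a_mj ~ N(0, latent_sd)`. A member taxon's log relative abundance is
`base_i + lambda_i * a_mj + eps_ij`, with `base_i ~ N(0,1)` (cross-taxon
abundance spread), loading `lambda_i ~ U(loading_range)`, and intrinsic
noise `eps_ij ~ N(0, dispersion)`. Background taxa omit the latent term.
Per sample, relative abundances are the softmax over taxa and counts are
one multinomial draw at `sequencing_depth` — a compositional count model
that mimics an already-rarefied table (all column sums equal).

**Keystones.** The first `keystone_per_module` taxa of each module are
planted hubs: loading fixed at 1.0 (above the member range), intrinsic
noise shrunk by `keystone_noise_factor` (default 0.25), and sign
`keystone_sign` (−1 = competitive: the keystone moves against its
module). Without this asymmetry a "keystone" would be statistically
exchangeable with members and would not emerge as a network hub, so the
ground truth the recovery tests assume would be vacuous. Ground truth
(`SyntheticTruth`) records module membership, latent activities,
keystone identities, within-module edges with signs (the product of the
two loadings' signs), substrate-labeled taxa, and noise-free traits.

**Two-condition studies.** One `generate_counts` call produces one
condition (2 × `n_samples_per_group` samples). The unamended/amended
contrast is built from two designs that differ only in `keystone_sign`
(+1 cooperative vs −1 competitive) and seed; each condition is analyzed
as a separate network, exactly as the original two sample sets were.

**Traits and SIP labels.** A trait is `coef * a_m + N(0, sd)` per the
`trait_model`; noise is keyed to sorted sample ids, so trait–sample
alignment is by id, not column position. The labeled set contains
`round(labeled_fraction * n_taxa)` taxa drawn without replacement and
always includes every keystone.

**Calibration.** The defaults are the study conditions of all tests and
of `scripts/acceptance.py`: 120 taxa (3 modules × 10 + 90 background),
30 samples per condition, `latent_sd = 0.45`, member loadings
(0.55, 0.8), `dispersion = 0.1`, depth 20 000. Two properties of
compositional data drove this choice and are worth knowing about:
(1) softmax closure couples every taxon through the per-sample
normalizing sum, so large latent swings both attenuate planted
associations and create spurious background correlations — background
taxa absorb most of that; (2) Pearson correlation between anti-varying
log-normal abundances is bounded well away from −1 once log-scale
swings exceed ~0.5 sd, so negative (competitive) edges are only
detectable at the 0.7 score threshold in a near-linear regime of modest
swings. The defaults sit where member–member associations straddle the
0.7 threshold (degree heterogeneity inside modules), keystone–member
associations sit clearly above it (planted hubs really are hubs), and
background pairs essentially never pass both correlation filters.

**What the generator does not emulate.** No sparsity/zero inflation
beyond multinomial sampling, no taxonomy or phylogenetic signal, no
sequencing-error structure, and within-taxon abundance swings milder
than field data often shows. Passing recovery tests therefore
demonstrate that the pipeline's inferential chain is correct and
calibrated on data satisfying its assumptions — not that field data of
arbitrary character would yield the same power.

## Ensemble association inference

Scores are computed on relative abundances for every taxon pair:
Pearson and Spearman correlations (signed, in [−1, 1]); Bray–Curtis
similarity `1 − dissimilarity` (in [0, 1]); Kullback–Leibler similarity
`exp(−symmetrized KL)` on pseudocounted, per-taxon renormalized
profiles. Defaults follow the study design: score threshold 0.7,
`alpha = 0.01`, 1000 permutations, BH correction.

**Permutation null.** Each replicate independently shuffles every
taxon's values across samples (destroys all between-taxon dependence,
preserves marginals; one shared shuffle serves all four measures).
Empirical p-values carry the +1/(N+1) correction. Two-sidedness:
correlations use `#{|null| >= |obs|}`; the non-negative similarities
double the smaller tail, `p = min(1, 2 min(hi, lo))`, so that mutual
exclusion (unusually *low* similarity) is as extreme as co-presence —
without this, no negative edge can ever reach significance, because two
of its four merged p-values would be pinned at 1.

**Tail resolution.** Inside `ensemble_network`, p-values in the
unresolvable region (< 10 null exceedances) are extended by a Gaussian
tail fitted to the per-pair null moments,
`p = min(p_emp, max(2 Phi(−|obs − mu|/sigma), 1e−12))`. With N = 1000
alone, every strong edge collapses onto the 1/1001 floor and the
selection-aware BH correction (below) then removes them all; the
parametric tail is the same mechanism ensemble co-occurrence tools use
(a z-score against the resampling null). `permutation_pvalues` itself
always returns the pure empirical values.

**Candidates and sign.** A pair becomes a candidate when at least
`min_support` of the *correlation* measures pass the score threshold in
absolute value and Pearson and Spearman agree in sign (conflicting
signs are dropped and logged). The similarities deliberately do not
count toward candidacy: after per-taxon renormalization, profiles of
unrelated taxa saturate both similarity scores above 0.7, which would
inflate the candidate universe quadratically and (measured) empty the
network beyond ~160 taxa. They still contribute evidence through the
merged p-value. Edge sign is the sign of the mean of the two
correlation scores; the unsigned similarities never vote on sign.

**Brown's method.** The four dependent p-values merge via
`psi = −2 Σ ln p` with `E = 2k`, `Var = 4k + 2 Σ cov_ij`,
`c = Var/2E`, `f = 2E²/Var`, and merged `p = chi2_f.sf(psi/c)`; zero
covariance reproduces Fisher's method exactly. The covariance of the
−2 ln p statistics is estimated from the shared permutation null over a
seeded random pool of ≤ 200 pairs (each replicate's p is its
within-null exceedance rank, transformed identically to the observed
p), then clipped to the nearest PSD matrix. A random pool rather than
the candidate pool avoids selection bias: dependence between measures
is a property of the measure quadruple, not of the selected pairs.

**FDR.** BH runs over the candidate p-vector with `m = n(n−1)/2`, the
number of pairs *tested*. The score filter selects exactly the pairs
with extreme permutation p, so correcting only within the survivors
would keep every chance-extreme pair under a global null; with the full
universe as `m`, null communities (200 independent taxa, 20 samples)
yield empty networks while planted edges pass comfortably. Edges with
`q < alpha` are kept, in canonical `taxon_a < taxon_b` order.

Group handling follows the source design: taxa must be present in every
sample of a group to enter that group's network (`filter_prevalent`),
and groups are inferred as separate networks.

## Network analysis

Topology (density, average clustering, path length and diameter on the
largest component, mean degree, positive/negative edge counts) treats
the graph as simple and undirected, ignoring edge sign except for the
sign counts. Modules come from seeded Louvain modularity maximization
(nodes inserted in sorted order for reproducible tie-breaks); modules
are indexed by descending size and modules smaller than 3 nodes are
relabeled background (−1). MCODE is implemented per its three stages —
vertex weight = (density of the highest k-core of the closed
neighborhood) × (that core's k); seeded greedy expansion admitting
neighbors with `w >= w_seed (1 − node_score_cutoff)` (default 0.2);
post-processing drops complexes without a 2-core, with optional haircut
(default on) and fluff (default off) — and reports possibly overlapping
complexes ranked by density × size, alongside (not instead of) the
Louvain partition, which is what Zi–Pi uses.

Node roles: `Z` is the z-score of the within-module degree against the
node's module (population sd; `Z = 0` when the module is
degree-regular), `P = 1 − Σ_s (k_is/k_i)²` (0 for isolated nodes,
flagged). Role thresholds default to the published values
(`Z > 0.25`, `P <= 0.62` for module hubs); the classical preset
(`Z > 2.5`) ships as `CLASSIC_THRESHOLDS` because the published
keystone Z values (2.53–3.12) all clear the stricter cut and the source
never resolves whether 0.25 was intentional. Neither preset is asserted
as "the" intended one.

## Eigengenes and trait correlation

A module eigengene is the first right-singular vector of the module's
standardized member × sample matrix (rows to mean 0, sd 1), unit norm,
computed on relative abundances after the same rarefaction used for
network inference. Sign convention: correlate non-negatively with the
member-average standardized profile (first-nonzero-positive as the
degenerate tie-break), which makes trait-correlation signs
reproducible. `variance_explained = s1²/Σ si²`.

Trait relationships use Spearman's rho with the t-approximation p for
n ≥ 10 and an exact full-enumeration permutation p below that (field
designs of this kind have as few as 6–9 replicates, where the
t-approximation is dubious). Constant vectors yield flagged rows with
undefined rho, excluded from the BH universe; q-values are adjusted per
correlation table, matching a heatmap-shaped analysis where the table
is the inferential unit. `export_downstream` emits aligned
samples × features and target tables for external model-fitting tools
(random-forest importance, SEM), which are out of scope here.

## Community metrics

Shannon uses natural log by default (base configurable); Chao1 is
bias-corrected, `S + F1(F1−1)/(2(F2+1))`, with the classical form by
flag (falling back to bias-corrected when F2 = 0, where it is
undefined). Rarefaction is a single seeded multivariate hypergeometric
draw per sample; repetitions are available via seeds. Bray–Curtis
distances feed classical metric-scaling PCoA, which reports the full
eigenvalue spectrum (negatives included, as Bray–Curtis is
non-Euclidean) and zeroes coordinates on non-positive axes; no
Lingoes/Cailliez correction is applied. AWCD reads one timepoint
(convention: 96 h), subtracts the blank, clamps negative wells to zero
(standard plate practice), and averages the 31 substrate wells, with
per-family means over the six substrate families. The metabolic
quotient is basal respiration divided by microbial biomass.

## Problem sizes and determinism

Test and acceptance runs use the default fixture (120 taxa, 30 samples,
1000 permutations; ~1 s per inferred network), 25-seed batteries for
recovery rates, a 10-seed 200-taxon null for FDR calibration, and
10 000 draws for the rarefaction law — sizes chosen so the whole suite
completes in a couple of minutes while keeping Monte-Carlo margins
comfortable. All randomness flows through explicitly passed integer
seeds (numpy `default_rng`); no global random state is touched.

## Known limitations

The Gaussian tail extension is an approximation beyond the permutation
resolution; its error matters only in the deep tail where edges are
unambiguous. Degenerate modules (all members at equal within-module
degree) give Z = 0 for everyone, so a keystone in a fully saturated
module cannot be distinguished by Z — visible at very strong signal
settings. MCODE's greedy expansion merges equally-weighted dense
regions connected by a bridge into one complex; this is inherent to the
published algorithm's admission rule. Compositional effects are
mitigated by background taxa, not modeled away: no SparCC/SPIEC-EASI
style regularization is attempted, by design.
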