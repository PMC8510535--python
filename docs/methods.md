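# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `ecoassembly` package: a pipeline for inferring how
microbial communities assemble along an environmental gradient, who the
network keystones are, and how community structure relates to ecosystem
multifunctionality — together with the synthetic metacommunity generator
used to validate every stage against planted ground truth.

## Rare/abundant classification

Each taxon's per-sample relative-abundance vector `a` is classified with
two thresholds, upper = 0.01 (1%) and lower = 0.0001 (0.01%):

| category | rule |
|---|---|
| AAT (always abundant) | min(a) ≥ upper |
| CAT (conditionally abundant) | max(a) ≥ upper, min(a) ≥ lower, not AAT |
| ART (always rare) | max(a) < lower |
| CRT (conditionally rare) | max(a) < upper, min(a) < lower, max(a) ≥ lower |
| MT (moderate) | lower ≤ min(a), max(a) < upper |
| CRAT (conditionally rare and abundant) | min(a) < lower, max(a) ≥ upper |

The upper threshold is inclusive and the lower exclusive, exactly as the
definitions are conventionally printed. The six predicates are mutually
exclusive and exhaustive over taxa with nonzero totals (property-tested on
10⁵ random profiles); zero-total taxa are dropped before classification
because their profile is undefined after rarefaction.

The binary grouping is abundant = AAT ∪ CAT ∪ CRAT and rare = ART ∪ CRT.
The alternative literal reading "rare = ART ∪ CAT" circulating in parts of
the literature contradicts CAT's own definition (a conditionally *abundant*
taxon); it is available behind `rare_group="art_cat"` for reproduction
purposes but is not the default.

## Rarefaction

Samples are subsampled to a common depth (default: the minimum sample
total) by a multivariate hypergeometric draw — true subsampling without
replacement of observed individuals, not a multinomial resample. A single
seeded draw is used; the expectation property (mean rarefied count =
depth × proportion) is verified empirically in the tests. Orientation of
input tables must be declared by the caller; auto-detection is deliberately
not attempted.

## Phylogenetic null models (SES.MNTD, βMNTD/βNTI)

MNTD is the mean patristic distance from each taxon present in a sample to
its nearest other taxon in that sample; βMNTD matches each taxon to its
nearest relative in the *other* sample and averages the two directed means:

    βMNTD(x, y) = ½ [ Σᵢ fᵢ · min_{j∈y} d(i,j) + Σⱼ gⱼ · min_{i∈x} d(j,i) ]

with f, g the within-sample relative abundances (uniform over the support
when unweighted). Abundance weighting is the default. Taxa shared by both
samples contribute zero (their nearest relative in the other sample is
themselves), so identical communities have βMNTD = 0. Note that some
implementations average the pooled nearest-neighbour list instead of the
two per-sample means; the two conventions agree for the abundance-weighted
statistic (cross-checked against picante in the tests) but differ for the
unweighted one when richness is unequal.

The null model is a "taxa labels" shuffle: tip identities are permuted on
the patristic distance matrix over all taxa of the analysed table, leaving
richness and abundances untouched. SES.MNTD and βNTI are
(observed − null mean) / null sd with 999 shuffles by default. One stream
of shuffles is shared by all sample pairs of a table — this keeps the
pairwise matrix internally consistent and lets each shuffle be evaluated
for every pair with a single matrix product (the per-sample
nearest-distance vectors `m_y[i] = min_{j∈support(y)} d(i,j)` are computed
once per shuffle, after which the βMNTD matrix is `½(F Mᵀ + (F Mᵀ)ᵀ)`).

When the null standard deviation is zero the score is undefined: a star
phylogeny (shuffling changes nothing), or a pair whose supports are
identical (βMNTD is 0 under every relabelling). Such entries carry a
`degenerate` flag and NaN score, are excluded from process proportions,
and are labelled `unassigned` in the partition. This arises naturally for
abundant sub-communities of well-mixed metacommunities, where a few
ubiquitous taxa occupy every sample.

Rare and abundant groups are analysed as separate sub-tables, each with
its own shuffle pool, matching the per-group presentation of assembly
results.

Calibration: under communities assembled by random label assignment,
|βNTI| < 2 holds in ≈95% of pairs (93–97% over ≥1000 simulated pairs in
the acceptance tests), and the Monte-Carlo null mean/sd agree with
exhaustive enumeration of all 720 tip permutations on 6-taxon tables to
within 5%.

## Taxonomic null model (RC_bray)

For each pair, the observed Bray–Curtis dissimilarity is compared with 999
null communities built per sample by (i) drawing the sample's observed
richness of taxa without replacement with probability proportional to
occupancy (fraction of samples occupied), (ii) giving each drawn taxon one
individual, and (iii) filling to the sample's observed total with a
multinomial weighted by regional relative abundance restricted to the
drawn taxa. Unweighted variants of both steps are available by flag.

    RC = 2 · (#{null BC < obs} + ½ · #{null BC = obs}) / n_null − 1  ∈ [−1, 1]

Ties count at half weight, making RC unbiased under exchangeability. All
25 (or 33) samples are nulled jointly per replicate, so one replicate
yields null Bray–Curtis values for every pair at once.

Calibration: on tables generated by this null's own process, |RC| < 0.95
holds in ≈95% of pairs. Because the null parameters (occupancy, regional
abundances) are re-estimated from the analysed table itself, shallow
tables with highly skewed pools show mild tail inflation; the calibration
study uses depth 2000 and a log-normal pool with σ = 0.5, where the rate
is comfortably above 90%.

## Assembly-process partition

Per pair, from (βNTI, RC_bray):

* βNTI > 2 → variable selection
* βNTI < −2 → homogeneous selection
* |βNTI| < 2 and RC > 0.95 → dispersal limitation
* |βNTI| < 2 and RC < −0.95 → homogenizing dispersal
* |βNTI| < 2 and |RC| < 0.95 → undominated

The printed rules are strict inequalities on both sides, so exact
threshold hits (|βNTI| = 2, |RC| = 0.95) fall in no bin; they are counted
as `unassigned` along with degenerate pairs, and process proportions are
reported over assigned pairs only. All five bins are always reported.

## Permutation tests

All permutation p-values follow `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`,
so the minimum attainable p is `1/(n_perm+1)` and never 0; the default is
999 permutations, one-sided (greater) for distance-matrix association.

* **Mantel** — (rank) correlation of the upper-triangle entries of two
  distance matrices, permuting sample labels of the first. Spearman by
  default (Pearson by flag). Because a label permutation merely permutes
  the condensed vector's entries, the ranks are computed once and all
  permutation replicates reduce to one indexed matrix product; this keeps
  the 500 × 999-permutation type-I calibration runs to seconds.
* **Environment fit** — the community distance matrix is embedded by PCoA
  (2 axes by default; negative-eigenvalue axes discarded), and R² is the
  squared multiple correlation of one environmental variable with its
  least-squares projection onto the axes; the null permutes the variable's
  values. Whether the original study fitted vectors to an ordination or
  worked directly on the distance matrix is not recoverable; the
  PCoA-vector-fitting interpretation is implemented and flagged.
* **EMF distance** — the Euclidean distance of multifunctionality used in
  the community–EMF Mantel test is |EMF_i − EMF_j| on the scalar index by
  default; the full 18-dimensional z-score vector is available by passing
  the z-matrix, since the scalar reading of "Euclidean distance of
  multifunctionalities" is not the only possible one.

Both tests hold their nominal type-I error (0.03–0.07 at α = 0.05 over
500 null simulations) and agree with exhaustive permutation enumeration at
n = 5–6 to within 0.03.

## Co-occurrence network and keystones

Edges connect prevalence-filtered taxa (≥50% of samples by default) whose
relative abundances have |Spearman ρ| ≥ 0.8 with Benjamini–Hochberg
adjusted p ≤ 0.05. The random-matrix-theory threshold selection used by
dedicated network pipelines is out of scope; the fixed correlation
threshold is a first-class configuration key so sensitivity can be
scanned. Modules are found by greedy modularity maximisation on the
unweighted, unsigned graph (deterministic for a given graph).

Per node, Zi is the within-module degree z-score (standardised by the
module's mean and *population* standard deviation; Zi = 0 when the module
sd is 0) and Pi = 1 − Σ_m (k_im/k_i)² the participation coefficient.
Roles: network hub (Zi > 2.5 and Pi > 0.62), module hub (Zi > 2.5,
Pi < 0.62), connector (Zi < 2.5, Pi > 0.62); everything else, including
exact threshold hits, is peripheral. Keystones = the three non-peripheral
roles. Isolated nodes have undefined Pi and are excluded. Under the strict
thresholds, sparse or strongly two-block networks can legitimately have
zero keystones.

## Ecosystem multifunctionality

Functions are z-scored per column (n−1 denominator; constant columns are
an error) and averaged per sample (the averaging approach). The EMF grand
mean is therefore exactly 0, which makes the ratio-based fold change
versus the control ill-behaved whenever the control mean is near 0 or
negative (a more negative treatment over a negative control yields a fold
change > 1). The ratio is reported for comparability, suppressed when the
control mean is within a configurable epsilon of zero, and the mean
*difference* in EMF units is always co-reported and is the recommended
effect measure. The 18 function names are configuration, not hard-coded;
tables with any number of functions run identically.

## Niche change points and environmental breadth

For one taxon along one gradient, candidate change points are midpoints
between consecutive sorted unique gradient values with at least 3 samples
per side. Each side scores IndVal = (side mean relative abundance / sum of
the two side means) × (side occurrence frequency); the change point
maximises the larger side's score, with direction z+ when the high side
wins. Ties are broken to the lowest candidate, and a taxon whose
candidates all tie is flagged uninformative. A bootstrap over samples
(500 replicates by default) gives a 5th–95th percentile interval, widened
if necessary to contain the point estimate.

This is deliberately the core indicator-threshold computation only. Full
TITAN — permutation-standardised z-scores, purity and reliability filters,
community-level sum(z) change points — is not reproduced; no parameters
for it beyond package defaults are recoverable, and the group-level
summary used downstream needs only the taxon-level thresholds.

Environmental breadth of a taxon group along a variable is the
interquartile range of the group's (informative) change points divided by
the variable's observed range ∈ [0, 1]; 0 means all taxa switch at the
same threshold (narrow breadth), and uniformly spread change points give
0.5. This is one defensible aggregation of taxon thresholds into a group
breadth and is labelled as such in outputs. Note the IndVal statistic
anchors change points at occupancy boundaries; taxa present in every
sample with smooth unimodal responses are driven toward extreme splits,
which is a known limitation of indicator-value thresholds without the
TITAN z-standardisation.

## Synthetic metacommunity generator

The generator emulates the downstream objects of a replicated,
gradient-structured amplicon field study: a rarefied-depth OTU table
(33 samples = 11 treatment levels × 3 replicates), a pure-birth phylogeny
with Brownian traits, an environmental gradient with derived edaphic
covariates (pH, SOM, DOC and two labile-Cd analogues, monotone in the
gradient with noise), and 18 gradient-responsive ecosystem functions
(function = a_f + b_f·env + noise, slopes Normal(mean effect, 0.5) so
signs mix).

Defaults: 300 taxa, 33 samples, depth 5000, log-normal pool μ = 0, σ = 2
(qualitatively reproducing the rare-biosphere shape: most OTUs rare, most
sequences in a few abundant taxa — a qualitative, not fitted, match),
Brownian rate σ_BM = 1, gradient −2…+2.

Scenarios:

* **selection** — sample-specific weights = pool ×
  exp(−(trait_z − env_s)²/(2σ_f²)) with σ_f = 0.4, where trait_z is the
  Brownian trait standardised across tips. Standardisation puts the niche
  width in trait-sd units so the gradient-to-niche geometry does not drift
  with the tree realisation; on the raw scale, recovery varied strongly
  from tree to tree. Pairs far apart on the gradient are filled by
  phylogenetically distinct taxa, giving βNTI > 2.
* **well_mixed** — every sample is a multinomial draw from the shared
  pool: minimal turnover, RC_bray → −1 (homogenizing dispersal) or
  |RC| < 0.95 (undominated).
* **dispersal_limited** — samples are grouped into ~1/subpool_fraction
  patches (default 4), each with a disjoint random subpool of the regional
  pool. The patch structure is essential: if every sample drew an
  *independent* random subset, the observed pair overlap would equal the
  occupancy-based expectation of the RC null and RC would centre on 0
  rather than +1. Localized (patch-shared, cross-patch-disjoint) subpools
  are also the ecological meaning of dispersal limitation: neighbours
  exchange migrants, distant sites do not.

Scenario recovery at these defaults over 50 generator seeds: variable
selection is modal with ≈67% of pairs under selection; homogenizing
dispersal + undominated cover ≈95% under well-mixing; dispersal limitation
is modal (≈75%) under patch-limited dispersal.

What the generator does **not** emulate: sequencing noise and chimeras,
taxonomic assignment error, compositional artefacts of relative-abundance
data, spatial autocorrelation within patches, interaction-driven
co-occurrence (network edges in synthetic data arise from shared
environmental response, not ecological interaction), and any calibration
to a particular survey's parameter values. Passing tests therefore show
the machinery is correct and calibrated, not that any particular field
system behaves like the generator.

## Numerical and computational choices

* Null replicate and permutation counts default to 999. The 50-seed
  scenario-recovery studies use 199 null replicates: the standardised
  scores enter only through threshold comparisons aggregated over
  thousands of pairs, where the extra Monte-Carlo noise of 199 versus 999
  replicates is negligible; single-dataset analyses keep 999.
* Null moments are accumulated streaming (sum and sum of squares) with the
  n−1 variance denominator; a null sd ≤ 1e-12 is treated as degenerate.
* Tie comparisons between null and observed Bray–Curtis use a 1e-12
  relative tolerance; permutation-test exceedance uses a 1e-12 slack so an
  identity permutation always counts.
* The pipeline writes TSVs with a fixed float format and records SHA-256
  digests in a manifest; identical configurations reproduce byte-identical
  outputs (every stochastic stage is seeded).
* Problem sizes in the test and acceptance studies (60-taxon calibration
  tables, 25 samples, 2–4 replicate tables, 200–500 type-I simulations,
  10 acceptance-script seeds per scenario) were chosen so the full
  validation runs in minutes on one core while keeping Monte-Carlo
  standard errors well inside the asserted bands.

## Known limitations

* βNTI power depends on phylogenetic signal in the trait driving
  selection; with weak signal, true selection is classified as stochastic.
* RC_bray estimates its null parameters from the analysed table; very
  shallow or very skewed tables inflate its tails (see calibration above).
* The fixed correlation threshold replaces data-driven (random-matrix)
  threshold selection; keystone counts are sensitive to it and should be
  read comparatively, not absolutely.
* The IndVal change point inherits indicator-value edge effects for
  ubiquitous taxa (above).
* Process proportions treat pairs as independent observations, as is
  conventional; they are not, and no uncertainty is attached to the
  fractions.
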