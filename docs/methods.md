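# Methods

## Scope and model overview

The package analyses a short bulk RNA-seq time course with one library
per time point and no replicates, the design typical of rapid
hormone-response experiments.  The chain is: RPKM normalization → exact
per-pair differential-expression testing → trend profiling →
highest-reciprocal-rank (HRR) co-expression network → Markov clustering
(MCL) into modules → hypergeometric module enrichment, with Livak qPCR
and hormone-ratio helpers for validation assays.  Every stage is a pure
function of its inputs plus an explicit seed, and the pipeline manifest
records all resolved parameters, so reruns are byte-identical.

## Differential expression without replicates

With a single library per condition the only tractable error model is
count-sampling noise.  The Audic–Claverie test conditions on the count
*x* in library 1 (sizes N₁, N₂) and evaluates the count *y* in library 2
against

    p(y | x) = C(x + y, y) · q^y · (1 − q)^(x+1),   q = N₂ / (N₁ + N₂),

the negative-binomial pmf with x + 1 successes and success probability
N₁/(N₁+N₂).  Tail sums run in log space (log-sum-exp over log-gamma
terms); the upper tail is accumulated in chunks until terms fall below
1e−16 of the running maximum, giving double-precision-exact sums that
the tests cross-check against both brute-force series summation and the
scipy negative-binomial tail.  The two-sided p is twice the smaller
tail, capped at 1 and floored at the smallest normal double (the point
mass at y keeps both tails mathematically positive).

Two numerical conventions worth knowing:

* Both tails include the observed point.  Under this convention the
  swap (x, N₁) ↔ (y, N₂) changes each tail by at most one point-mass
  term, so two-sided p-values agree across the swap only up to
  2·max(point masses); the exactly swap-invariant statistic would be
  min(P(Y ≤ y), P(Y > y)).  The inclusive convention is kept because it
  is the conservative, conventional choice.
* BH adjustment is applied within each comparison separately, since
  each library pair is a separate family of tests.

A gene is called for a comparison when (inclusively) q ≤ max_fdr,
|log₂ ratio| ≥ min_abs_log2, and the larger of the two samples' RPKM
values ≥ min_rpkm — the max so a gene silent in one condition stays
eligible.  Fold changes default to pseudocounted RPKM
(log₂((b+1)/(a+1)); a raw-count route is available), with the later time
point in the numerator.  Preset threshold triples: strict (2, 0.05, 2),
lenient (0, 0.05, 2) and the network-eligibility set (−, 0.05, 1.5).

**Calibration caveat.**  The conditional model is exact for Poisson
(technical) sampling only.  The null false-positive rate is therefore
checked under Poisson simulation, where it is far below nominal
(≈ 1e−4 at FDR 0.05).  Under biological-scale overdispersion the
no-replicate test is intrinsically anticonservative — background genes
acquire tiny p-values — which is a property of the design, not of the
implementation; the synthetic studies below quantify its consequences
rather than hide them.

## Trend profiles

Each gene's two transitions are classified against a flat threshold of
1.0 log₂ unit by default (no empirical rule exists for this constant; it
mirrors the fold-change spirit of the DEG filters and is exposed in
config).  The 3×3 transition grid minus the uninformative flat–flat cell
maps to indices 0–7 via 3·s₁ + s₂ (down = 0, flat = 1, up = 2), shifting
indices past the removed cell down by one.  Inverting a series
(negating both log₂ transitions) maps profile i to 7 − i for all eight
profiles; this, not time reversal, is the mirror symmetry of the
indexing and is what the tests assert.

Profile over-representation is scored by permutation: time labels are
shuffled independently within each gene and a profile's p-value is the
fraction of permutations whose count reaches the observed one, with the
observed arrangement counted in (add-one rule, so p ∈ (0, 1] always —
a deliberate small deviation from the plain fraction).

## HRR network

Correlations are Pearson on log₂(RPKM + 1) (variance stabilization;
zero-variance genes get r = 0 and are reported).  For each gene,
neighbors rank by descending r with ties broken by ascending gene order
(ordinal, deterministic); negative correlations simply rank last.
HRR(A,B) = max of the two mutual ranks; an edge survives iff
HRR ≤ cutoff (30 by default, inclusive), weight exactly 1/HRR.

With only three samples Pearson r is nearly degenerate (|r| piles up
near 1 — for two independent normal 3-vectors P(|r| > 0.99) ≈ 0.09
analytically, which the generator's null test uses as its yardstick).
The construction stays well defined; a warning is emitted for profiles
shorter than four samples, and module recovery in this regime leans on
HRR's rank structure rather than on r magnitudes.

Topology statistics follow the conventional graph-analyzer panel:
clustering coefficient averaged over nodes of degree ≥ 2, density =
mean degree/(n−1), heterogeneity = CV of degree, centralization =
n/(n−2)·(max degree/(n−1) − density), diameter/radius as max/min
eccentricity over non-isolated nodes within components, characteristic
path length over ordered connected pairs.  Note a radius of 1 cannot
co-occur with a diameter of 7 under these (or any standard
single-definition) eccentricity semantics; the package reports the
standard value.

## Markov clustering

MCL is implemented from scratch on the dense column-stochastic flow
matrix: expansion (matrix power 2), inflation (elementwise power 1.6,
column renormalization), pruning of entries below 1e−5 with
renormalization, until the matrix changes by less than 1e−6 or 100
iterations (non-convergence returns the current clustering with a
warning, never silently).  Self-loops equal each node's maximum incident
edge weight (1 for isolated nodes) to damp period-2 flow.  Clusters are
the attracted basins of the limit matrix's attractor systems; nodes
attracted by several systems go to the largest cluster (smallest id on
ties), so the output is always a partition.  Cluster ids are 1-based in
decreasing size order; clusters of ≥ 15 genes are flagged as modules
(the size floor conventional for reporting co-expression modules).

## Enrichment

Upper-tail hypergeometric p per (module, term) with the background
defaulting to the annotation universe (a network-restricted background
is a flag; the choice is required to be explicit in the CLI).  Terms
mapping fewer than two module genes are excluded before testing and
before the BH adjustment; significance is q < 0.05.  "Hochberg FDR" is
read as Benjamini–Hochberg (plain Hochberg step-up available behind a
flag).  Terms are flat identifiers — no ontology DAG propagation.

## Assays

2^−ΔΔCt: replicates averaged on the Ct scale, multiple reference genes
combined by the arithmetic mean of their Cts (geometric mean of linear
quantities), ΔΔCt against a designated calibrator condition; the
calibrator against itself is exactly 1.  Hormone ratios are elementwise
division on a shared time grid with zero denominators rejected by time
point.

## Synthetic data

The generator emulates the 0/2/4 h design: per-gene baseline log₂
abundance ~ Normal(5, 2) (arbitrary units — only relative abundance
matters), module members share a latent log₂ profile plus
Normal(0, within_noise_sd) deviations, DE genes get a log₂ offset at one
time point, gene lengths are uniform on 500–3000 bp.  Expected counts
are library_size × per-sample relative abundance (2^z normalized per
sample), so planted log₂ fold changes are expected fold changes up to
composition effects: planting much up- or down-regulation shifts the
per-sample normalizer, which is exactly the compositional artifact real
RNA-seq has.  Counts are gamma-Poisson (negative binomial) with shape
r = nb_dispersion, variance μ + μ²/r; r = 10 by default
(biological-scale overdispersion, extra CV ≈ 0.32), r = ∞ gives exact
Poisson.  Library sizes default to 10⁶ reads — a deliberate scale-down
that keeps per-gene depth (≈ thousands of reads) in the regime where
test behavior matches full-depth libraries.

Annotation simulation gives each planted module one enriched term
(received by members with probability 0.8 by default) against a
background association rate (0.05–0.1), with extra pure-background terms.

What the generator does **not** emulate: read-level artifacts (mapping,
GC, length bias within a gene), isoforms, correlated background
structure beyond the planted modules, and annotation realism (flat
terms, no DAG).  Passing recovery tests therefore demonstrates the
algorithms recover planted structure under honest count noise, not that
the biological conclusions of any particular study are right.

## Recovery studies and problem sizes

The acceptance studies run at deliberately compact sizes chosen so each
estimate's Monte-Carlo error is small relative to the property checked:

* **Module recovery**: MCL at inflation 1.6 on a constructed
  well-separated network (3 × 30 nodes, within-weight 1, between-weight
  1/30) gives adjusted Rand index 1.0 (ARI by direct pair counting).
* **DE recovery**: genes planted at |log₂FC| = 3 (10 per dataset, 200
  genes, default dispersion) are recalled by the strict filter at a true
  rate ≈ 92%; the test pools 100 seeds (1000 planted genes) so the ~1%
  standard error resolves the 90% bar.  The misses are draws whose
  realized fold change genuinely fell below 2 under overdispersion —
  the caller reports what the data show.
* **Enrichment recovery**: with a 50-gene module in a 1000-gene
  background and rates 0.8 vs 0.1, the planted term tops its module's
  ranking with p < 1e−6 in ≈ 100% of draws.
* **Null calibration**: 500-gene Poisson nulls, 50–100 seeds.
* **End-to-end**: a 1000-gene pipeline with three planted 30-gene
  modules under Poisson noise yields exactly the three planted modules
  with their terms significant.  Module size 30 is intentional: it does
  not exceed the HRR cutoff, so planted modules stay internally
  complete.  Under overdispersed counts or larger modules the 3-sample
  correlation degeneracy fragments modules and background genes leak
  through the network filter — realistic behavior documented here so the
  clean fixture is not mistaken for a general guarantee.

## Known limitations

* The exact test's validity is limited to technical sampling noise; do
  not read its q-values as replicate-aware error control.
* Three-sample Pearson correlation carries very little information per
  pair; HRR + MCL recover strong planted structure but fragment weak or
  overlapping modules.
* The trend flat-threshold and the module-size floor are reporting
  conventions, not inferred quantities.
* Enrichment treats terms as flat labels; propagate ontology parents
  beforehand if hierarchical semantics are wanted.
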