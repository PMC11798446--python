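# Methods

This note documents the statistical models, algorithmic conventions and
design choices behind `crosskey`, in the order the pipeline runs them.

## Preprocessing and differential expression

**Scale detection.** Public array matrices arrive either as linear
intensities or already log2-transformed. A matrix maximum above 100 is
taken to mean linear scale and `log2(x + 1)` is applied; the caller can
override with `force_log2`. Negative values under a linear reading are an
error.

**Quantile normalization.** Every sample is forced onto the mean empirical
distribution: the value of rank *r* in a column is replaced by the mean of
the *r*-th order statistics across columns. Tied values receive the average
of the quantile means their ranks span, which makes the transform exactly
idempotent (verified by test). Normalization runs per dataset, before probe
collapsing, so the test statistics see a common distribution per sample.

**Moderated t-test.** For probe *g* with pooled two-group residual variance
s²_g on d = n₁ + n₂ − 2 degrees of freedom, the posterior variance is

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d)

and the moderated statistic t_g = Δ_g / (s̃_g √(1/n₁ + 1/n₂)) is referred
to a Student t with d₀ + d degrees of freedom (Δ_g = case mean − control
mean; the fold-change sign convention is case minus control throughout).
The prior (d₀, s₀²) is estimated by matching the first two moments of
log s²_g to the scaled-F sampling model: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of the sample variance of
e over ψ′(d/2) determines d₀ through the trigamma inverse (Newton
iteration), and s₀² follows from the mean of e. When the excess is not
positive the prior degrees of freedom are infinite and every probe's
variance is pinned to s₀² = exp(mean e); the t reference then has infinite
df (normal). Zero-variance probes are excluded from estimation; if all
probes have zero variance the fit errors out. Limits are tested: d₀ → 0
recovers the ordinary pooled t, d₀ → ∞ the fixed-variance z-like
statistic.

**Multiple testing and collapsing.** Benjamini–Hochberg runs per dataset
(statsmodels' step-up implementation behind a validating wrapper). Testing
happens per probe; a gene with several probes is represented by the probe
with the smallest adjusted p (ties: lexicographically smallest probe id),
and that probe's expression row stands for the gene in all later stages.
Probes with blank symbols are dropped at collapsing. DEG thresholds are
|log2FC| ≥ 1.2 (inclusive) and adjusted p < 0.01 (strict).

## Set combining

Gene sets are uppercase symbol sets with provenance names. Per-platform
unions (icDEGs) and the cross-platform union (gcDEGs) guarantee
monotonicity: every dataset's DEG set is contained in its platform union,
and every platform union in the grand union — the pipeline's central
no-loss property, asserted as an invariant test. When unions merge
conflicting per-gene directions the gene is marked `discordant` rather than
resolved. Venn summaries enumerate exact membership-pattern counts for up
to six sets. The necessity analysis contrasts the union construction with
the five intersection-based alternatives (per-platform common sets, the
all-dataset common set) and reports per-key-gene presence flags.

## SVM discriminative filter

Each candidate gene is evaluated independently per dataset on its single
expression feature: a stratified 80/20 split, standardization fitted on the
training portion, an RBF-kernel SVM grid-searched over
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1, 1} with stratified,
shuffled 5-fold CV, and the gene's dataset score is the best CV accuracy.
The 20% hold-out accuracy is computed and logged but takes no part in
selection (the selection statistic is the CV accuracy on the training
split). Scores are averaged over the datasets containing the gene; the
ranking sorts by mean accuracy, then dataset count, then symbol, and
selection requires mean accuracy strictly greater than 0.95.

Determinism: the split and fold seeds derive from SHA-256 of
`(seed, gene symbol)`, and samples are put in canonical id order before
splitting, so results are identical regardless of evaluation order, worker
count, or input column permutation.

A caveat documented by the null tests: because the reported score is the
*maximum* CV accuracy over a 16-point grid, its null distribution is
optimistically biased (≈ 0.44–0.70 over 50 null seeds at n = 60 rather
than centered tightly on 0.5). This bias is far below the 0.95 selection
bar, so null genes essentially never pass, but the per-gene scores should
not be read as unbiased accuracy estimates.

## Network analysis

**Graph construction.** Edge lists carry confidences in [0, 1]; if any
value exceeds 1 the column is read as the 0–1000 STRING scale and divided
by 1000. Edges at or above the threshold (default 0.70, inclusive) are
kept; self-loops dropped; duplicate pairs keep the maximum confidence;
nodes exist only through surviving edges. In the pipeline the graph is
restricted to the SVM-selected genes before construction.

**MCC.** Maximal cliques are enumerated with networkx's Bron–Kerbosch
(pivoting); MCC(v) sums (|C|−1)! over maximal cliques of size ≥ 2
containing v. On triangle-free graphs this equals the degree (tested), and
the implementation is checked against a brute-force subset-enumeration
oracle on random graphs. Enumeration is bounded by an explicit clique
budget (default 10⁶) and fails loudly rather than truncating. Hub
selection takes the top-20 by MCC with ties broken by degree, then symbol;
MCC is computed on the full graph, not per component.

**MCODE.** Vertex weight = k_max × density of the highest k-core of the
vertex's *closed* neighborhood, zero when the degree is below 2 or the
neighborhood has no core at level ≥ 2. Complexes grow breadth-first from
unvisited seeds in decreasing weight order (depth ≤ 100), admitting
unvisited neighbors with weight ≥ (1 − 0.2) × seed weight; each vertex
joins at most one complex. The haircut takes the 2-core of the complex
(equivalent to repeatedly removing singly-connected vertices); fluff is
off. Module scores follow the ordered-pair convention: a module with n
nodes and e undirected edges reports 2e "edges", density 2e/(n(n−1)) and
score density × n, so a complete 7-node module reports 42 edges and score
exactly 7.0 — the convention under which published module node/edge counts
(7 nodes / 42 edges) are consistent. Hub-module genes are the union of
modules with score ≥ 6 and ≥ 6 nodes.

## Literature meta-hubs and the key-gene intersection

The packaged snapshot (`data/literature_hubs.tsv`) preserves 48 prior
studies' hub-gene lists token-for-token, typos included; a separate
human-reviewed alias map normalizes evident variants (e.g. DK1 → CDK1,
RACGAP → RACGAP1, one fused token expanding to MELK;PBK). Tokens shorter
than two characters are reported as unresolved fragments, never silently
dropped. Both the raw-token and normalized unique counts are exposed
because published summary counts rarely state which reading they use; the
snapshot gives 148 raw / 137 normalized, bracketing the commonly cited
138. The meta-hub set is the union over studies; alias application is
idempotent (normalized symbols are fixed points, tested).

Key genes are the intersection hub ∩ module ∩ meta. Although the combining
formula is sometimes typeset as a union in this literature, only the
intersection is consistent with a result of six common genes from sources
of sizes 20/13/138, and the intersection is what is implemented. Empty
inputs produce an empty result with a warning, not an exception.

## Validation

**AUC** is computed by the rank-sum identity (pair counting with half
credit for ties) rather than by fitting a logistic regression: with a
single covariate the fitted logistic score is a monotone function of the
covariate, so the ROC and AUC are identical and the optimizer dependency
is unnecessary. The identity AUC = U/(n₁n₀) is property-tested against
explicit pair enumeration.

**Median split** assigns value > median to "high", ≤ median to "low"
(ties to low); a constant expression vector is a degenerate-split error.
Risk groups derive purely from expression, never from outcome.

**Kaplan–Meier** uses lifelines' product-limit estimator, returned as a
(time, survival) step table and checked against hand-computed fixtures.

**Log-rank** is implemented directly (observed − expected with
hypergeometric variance at each distinct event time; χ²₁ reference) so
that per-group observed/expected counts are part of the result; it is
cross-checked against lifelines on random data and against a hand-computed
four-subject fixture (χ² ≈ 2.882). Event times where only one group
remains at risk contribute O − E = 0 and zero variance, preserving label
symmetry.

**Cox regression** is a from-scratch univariate Newton–Raphson maximizer
of the Breslow partial likelihood with analytic score and information
(risk-set sums accumulated over descending time order), convergence at
|Δβ| < 1e−8 within 50 iterations, step damping at |Δβ| ≤ 5, and an
explicit non-converged flag for monotone likelihoods (perfect risk-order
separation). Breslow ties were chosen over Efron for transparency of the
closed-form derivatives; with untied event times the two coincide, which is
how the fit is cross-checked against lifelines (Efron-only). The score
test at β = 0 equals the log-rank statistic for a binary covariate, and
this equivalence is asserted numerically.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k | N, K, n) via scipy, BH-adjusted within each collection. The
significance flag follows the raw p < 0.05 (adjusted values reported
alongside), and the universe defaults to the union of term members but
should be set to the measured gene set. Real GO/KEGG databases are out of
scope; collections arrive as GMT files.

## Synthetic studies

The generator emulates the *layout* of a multi-platform case/control
compendium, not array physics:

- **Universes**: three platforms of 240 genes sharing a 180-gene core,
  each with private genes — private genes are what make intersection-based
  combining lossy. All planted genes sit in the core.
- **Expression**: per-gene baselines drawn once per platform
  (Uniform(4, 10), log2 scale) so platforms differ in level without an
  explicit batch model; 1–3 probes per gene; 10% of probes lose their
  symbol annotation (planted genes exempt so ground truth stays
  recoverable — blank probes are dropped downstream regardless); cases
  shifted by the planted log2 effect; i.i.d. Gaussian noise, sd 0.5.
  Defaults: 30 samples per group, ten planted genes at |effect| 2.5–3.0
  (both directions), of which the first seven form the planted module.
- **Interactions**: planted module pairs connected with probability 1 at
  confidence ≥ 0.9; background pairs with probability 0.003 at confidence
  Uniform(0.2, 0.95).
- **Survival**: 374 patients; exponential event times with log-hazard
  0.7 × centered expression of a designated planted gene; independent
  Uniform(0, T_max) censoring with T_max solved numerically to
  approximate a 30% censoring fraction.
- **Literature**: ten pseudo-studies covering every planted gene plus
  decoy symbols absent from all universes, so the meta-hub union is a
  superset of the planted genes without adding spurious intersections.
- **Determinism**: each artifact draws from its own RNG stream seeded by
  the master seed plus a SHA-256 digest of the artifact's name/platform/
  replicate, so artifacts are mutually independent, order-insensitive and
  byte-identical across reruns (tested on the written files).

What passing on this generator does **not** show: robustness to batch
effects, probe-level intensity artifacts, correlated noise between genes,
non-Gaussian heavy tails, or annotation ambiguity beyond blank symbols.
A quantile-normalization side effect worth knowing: with only a few
strongly shifted genes, forcing all samples onto a common distribution
attenuates planted log2 fold changes slightly (≈ 2.5–2.9 observed for a
planted 3.0), which is the expected behavior of the method, not a bug.

## Problem sizes in the test suite

Unit and property tests run on hand fixtures and scaled-down studies
(60-gene universes, 20 samples per group). Simulation checks use 1000
null replicates for the log-rank type-I error (60-patient cohorts), 100
replicates of 500-patient cohorts for Cox CI coverage, 20 seeds for the
planted-vs-null SVM separation, and the full default configuration for the
end-to-end recovery check, which is run twice to assert per-seed
determinism. These sizes were chosen to give stable pass/fail behavior on
a single CPU while exercising each statistical property at a scale where
its asymptotics apply.

## Known limitations

- Two-group contrasts only; no covariates, array weights or multi-factor
  designs in the differential-expression stage.
- The SVM filter is univariate by design; no multivariate models or
  alternative kernels.
- MCC on graphs with pathological clique structure hits the enumeration
  budget and fails explicitly rather than approximating.
- The Cox fit is univariate with Breslow ties; no time-dependent
  covariates.
- Published per-cohort DEG counts and validation AUCs from the real
  GEO/TCGA compendia are not reproduction targets here — they depend on
  external downloads, array annotation versions and STRING snapshots that
  are deliberately outside this package's scope.
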