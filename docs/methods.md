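# Methods

## The model and its assumptions

`stagesig` targets expression studies of an ordered disease series: samples
from 8 histological stages (the first two, normal epithelium variants,
pooled as the control group), measured on a log2-scale expression platform.
The pipeline assumes expression values are already normalized and log-scaled
— fold changes are therefore differences of group means, and the signed fold
change is reported as `2^d` for a log2 difference `d ≥ 0` and `−2^(−d)`
otherwise, so down-regulation reads below −1.

### Moderated differential expression

For each non-control stage the per-gene statistic is a pooled two-sample t
whose variance is shrunk toward a common prior,

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),

with `d_g` the pooled degrees of freedom and `(d₀, s₀²)` estimated across
genes by method-of-moments on `log s²_g` (digamma/trigamma moment matching,
trigamma inverted by Newton iteration).  The moderated t is referred to a t
distribution on `d₀ + d_g` degrees of freedom (normal when `d₀ = ∞`, exact
ordinary t when moderation is off, i.e. `d₀ = 0`).  P-values are BH-adjusted
within each contrast; the default filter is adjusted p < 0.05 and
|signed FC| > 1.5 (a raw-p mode is config-exposed).  Survivors are merged by
union across contrasts with per-gene provenance.  Note that BH controls the
FDR per contrast; the union of six contrasts does not inherit the 5% bound —
at the synthetic reference conditions the union FDR measures ≈ 0.1–0.25.

### Clustering centrality and gatekeepers

On a cleaned simple undirected interactome (duplicate and self-loop edges
removed, optional taxon filtering at load), each node's clustering
centrality is `C_i = 2E_i / (k_i(k_i−1))` with `E_i` the number of edges
among its `k_i` neighbors (computed as the node's triangle count, an exact
integer).  Gatekeepers are the nodes with `C_i` exactly 1 — tested in
integer arithmetic as `2E_i = k_i(k_i−1)`, never floating point — and degree
at least 2.  Degree-0/1 nodes, where the formula is undefined, take `C = 0`
and are never called: a gatekeeper must bridge at least two interconnected
hubs.  The triangle K₃ satisfies the definition at every node; this
degenerate case is documented rather than special-cased.  Supporting
operations: induced subnetwork on a gene list (unmapped genes reported, not
dropped silently), largest connected component (ties broken toward the
component containing the lexicographically smallest node), and first/second-
order edge closures around a seed set with edge-coverage fractions.

### Two-round coefficient reduction

The stage classifier is a softmax multinomial logistic regression with L2
penalty (scikit-learn lbfgs, deterministic to solver tolerance).  Features
are z-scored per gene before fitting — without a common scale the
coefficient-magnitude threshold below would be meaningless.  After fitting,
the class × gene coefficient matrix (intercepts excluded) is standardized
jointly to zero mean and unit SD, and a gene is kept when its largest
absolute standardized coefficient across classes strictly exceeds 0.78.
Train-and-select runs twice; the second selection is a subset of the first.
Strict inequality, joint (rather than per-class) standardization and the
max-over-classes aggregation are all config-exposed choices.

A crucial empirical property, established by pre-build simulation: the
0.78-SD rule only reduces when the fitted coefficient distribution is
heavy-tailed.  If all non-signal genes are independent noise, their
standardized coefficients are approximately standard normal and the
max-over-8-classes rule keeps essentially every gene (P(max |z| > 0.78) ≈
0.99 under normality) at any effect size or regularization strength.  Real
microarray data escapes this because genes are strongly co-expressed; the
synthetic generator therefore reproduces that structure (below).

### Evaluation and the random-signature null

Models are trained and evaluated on the same records — the protocol the
reduction procedure was originally described with (a cross-validation mode
exists but is off by default, for fidelity).  Both plain accuracy and the
macro-averaged per-class Jaccard index `TP/(TP+FP+FN)` are always reported:
in this literature "Jaccard index" is used both for the proportion of
correct classifications (= accuracy) and for the macro average, so the
package computes both and uses macro-Jaccard for the null comparison.  The confusion matrix is stored with true classes on rows,
predictions on columns.

The null control trains one classifier per random gene set (uniform draw
without replacement, sets independent, size = the signature's) with the
identical protocol, and reports
`empirical_p = (1 + #{null ≥ observed}) / (n_sets + 1)`.

The permutation calibration check (labels permuted, no signal) evaluates a
*fixed* gene set against a fresh null on the permuted labels, and measures
how often the fixed set's score falls inside the null's central 95%
interval.  The fixed set must be exchangeable with the null draws — a
random gene set held constant across trials.  Two things would break the
check and are deliberately avoided: re-selecting the signature on each
permutation (selection overfits the permuted noise and biases the observed
score upward), and using the planted ramp genes as the fixed set (their
mutual correlation differs from the module background, so their span offers
more usable overfitting directions and their score sits above the null even
with no label signal — a covariance artifact, not miscalibration).

### Fisher enrichment

Per gene set a 2×2 table (in-set/out-of-set × in-input/out-of-input) over a
fixed universe is tested two-sided (sum of hypergeometric probabilities no
larger than the observed table's); expected overlap is
`input × category / universe`; direction is over/under by comparison with
the expectation (`none` on exact ties).  FDR is computed across exactly the
sets supplied — printed FDR values from external databases depend on the
full collection tested there and are not reproduction targets.  Symbol
matching is exact and case-sensitive; no alias resolution.

## The synthetic generators

**Expression.**  Planted genes carry an additive stage effect: under the
default `ramp` profile the mean at stage index j (0-based) is
`baseline_mean + j·effect_size` (log2 units); a `step` profile (shift from a
configurable stage onward) is available.  Planted genes receive independent
Gaussian noise of SD `noise_sd`.  The non-planted background defaults to a
block co-expression structure: each gene follows exactly one of `n_modules`
latent module activities (i.i.d. standard normal per sample,
stage-independent) with a signed loading drawn from ±U(0.9, 1.1), plus
idiosyncratic noise of SD `module_idio_sd`.  `n_modules = 0` gives a fully
i.i.d. background, used for the p-value-uniformity and false-positive-rate
null checks.  Defaults (chosen once, by pre-build Monte-Carlo at the
reference conditions, and frozen): 2000 genes, 15 planted, effect 2.0,
noise 1.0, 10 modules, idiosyncratic SD 0.01, per-stage sample counts
13, 14, 15, 13, 13, 12, 13, 14 (the stated group sizes of the bronchial
carcinogenesis series this design emulates; they sum to 107).  The default
L2 strength 0.7 comes from the same pre-build scan — published applications
of the procedure leave the regularization unstated.

What the background emulates, and what it does not: it reproduces the one
feature of real microarray data that the reduction rule's behavior hinges
on (strong gene-gene correlation concentrated in modules) but not probe-
level artifacts, dye effects, array normalization, heavy-tailed expression
distributions, or stage-correlated confounding.  Passing recovery tests
therefore show that the implemented procedure behaves as intended on data
with realistic correlation structure — not that it would recover a true
signature from any particular real data set.

**Interactome.**  Background topology is Barabási–Albert preferential
attachment (m = 2).  Hubs form a clique and each additionally attaches to
`hub_degree` random background nodes.  Each gatekeeper attaches to exactly
`gatekeeper_hubs` (default 2) hubs and nothing else, so its centrality is 1
by construction.  A repair pass then eliminates *accidental* centrality-1
nodes: for each offender an edge is added to a node sharing no neighbor
with it, which lowers the offender's C below 1, cannot raise the partner's
C, and perturbs no third node's neighbor-edge count; iterated to a fixed
point.  Planted gatekeepers consequently round-trip exactly through
detection.

## Numerical choices and degenerate inputs

- Gatekeeper equality is integer arithmetic; no tolerance parameter exists.
- The trigamma inverse runs Newton from `x = 0.5 + 1/y` (75 iterations,
  relative tolerance 1e-12); a non-positive excess variance of the log
  variances yields `d₀ = ∞` (pure prior, normal reference distribution).
- Zero residual variance with a zero mean difference gives t = 0, p = 1;
  with a nonzero difference, t = ±∞, p = 0; all-zero variance across genes
  is an error.
- Coefficient standardization uses the population SD; an all-equal
  coefficient matrix (e.g. a single-feature binary fit) yields zero z-scores
  in training and an explicit error when standardized directly.
- An empty round-1 selection raises with advice to lower the threshold; the
  sentinel threshold `SELECT_ALL = −inf` turns both selections off.
- All pipeline randomness flows from one root seed split per stage with
  `numpy.random.SeedSequence`; simulation and null seeds must differ —
  seeding both with the same integer makes the null's first k-subset draw
  literally reproduce the planted-gene draw (same generator stream).
- Artifacts are written with a fixed float format (`%.10g`) and sorted keys
  so reruns are byte-identical and manifest SHA-256 hashes match.

## Problem sizes used in tests and the acceptance script

Recovery and null checks run at the reference conditions above (2000 × 107
matrix), with 10 simulation seeds for recovery, 100-set nulls, and 20
permutation trials; the enumeration oracle for clustering centrality covers
100 random graphs of up to 200 nodes; the DGE recovery check uses 1000
genes with 50 planted.  These sizes were chosen so the full suite and the
acceptance script each complete in about a minute on a single CPU while
leaving every statistic well away from small-sample degeneracy.

## Known limitations

- Published applications of this procedure to a deposited bronchial
  carcinogenesis expression series report values such as a signature
  Jaccard of 0.92 against a null maximum of 0.29 and a 41,067 → 800 → 15
  gene reduction; those numbers depend on that series and on unstated
  standardization and regularization choices.  They are structural
  templates here (the package reproduces their *shape* on synthetic data),
  not numerical targets.
- Train-equals-test evaluation overstates generalization by construction;
  the protocol is kept for fidelity and the null comparison is the
  corrective lens.  With ~107 samples, 8 classes and 15 features a softmax
  model has enough parameters to interpolate, which is why null Jaccard
  values are far above chance yet far below the observed signature.
- The union-merge of per-contrast BH lists does not control a global FDR.
- Enrichment assumes exact symbol harmonization; probe-to-symbol collapse
  keeps the probe with the largest |t| per symbol and happens only at the
  network boundary.
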