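# Methods

## Problem and model

A directed regulation `source → target` in a signaling pathway carries a
sign: the source either activates or inhibits the target. `edgesign`
treats sign inference as binary classification over annotation *pairs*.
Given annotation catalogs (GO terms or domain accessions, handled as
separate namespaces and never mixed in one model), the candidate
features of an interaction are the Cartesian product
`annotations(source) × annotations(target)`.

**Enrichment ratio.** For each pair occurring in a labeled interaction
set, with `N` interactions overall, `M` of them activations, `n`
containing the pair and `m` activations containing the pair:

    ER = (m/M) / (n/N)

An interaction contributes at most 1 to `n` and `m` per pair regardless
of how many ways the pair could be formed from its annotations. The
reference class is fixed to activation: one ER per pair is sufficient
for a binary problem (ER > 1 ⇒ activation-leaning, ER < 1 ⇒
inhibition-leaning). Pairs that never occur are not represented; no
pseudocounts are added.

**Significance.** ER is screened with the exact hypergeometric tail:
drawing `n` interactions without replacement from `N` of which `M` are
activations, the p-value is the upper tail `P(X ≥ m)` when ER ≥ 1 (the
tie ER = 1 takes this branch; the comparison `m/M ≥ n/N` is made in
exact rational arithmetic) and the lower tail `P(X ≤ m)` when ER < 1.
Tail terms are summed in log space (`gammaln` + `logsumexp`); on small
counts the result matches exhaustive enumeration beyond twelve
significant digits (tested). Multiple testing is controlled across all
tested pairs with Benjamini–Hochberg at α = 0.05 by default
(Bonferroni and no correction are available); `significant` means
q ≤ α.

**Classifier.** Features are the raw ER values of the significant pairs
(a `log2` option exists but raw ER is the default), absent pairs are
implicit zeros, and the model is binomial logistic regression

    P(activation | x) = 1 / (1 + exp(−(β₀ + β₁·x)))

fitted by minimizing the total negative log-likelihood plus
`λ‖diag(s)β₁‖₁` (L1, default) or `(λ/2)‖diag(s)β₁‖₂²` (L2), where `s`
holds the per-feature standard deviations. Penalizing standardized
coefficients (scale-only, no centering, as in glmnet) matters here:
inhibition-associated pairs have ER ≈ 0.2 and would otherwise need
coefficients ~5× larger than activation pairs for the same effect,
so an unstandardized L1 path drops them first. The intercept is never
penalized; after the solver returns, the intercept is polished by a
one-dimensional Newton step (its conditional optimum is unpenalized
and convex), which also repairs the saga solver's under-converged
intercept at very strong penalties. Ties at P = 0.5 predict
activation, the majority class.

**λ selection.** By default λ is chosen by inner stratified 5-fold CV
over a log-spaced grid (10⁻¹…10³) with the one-standard-error rule:
the largest λ whose mean fold accuracy is within one SE of the best.
Plain argmax-accuracy CV systematically overselects features; the 1-SE
rule is the standard guard and measurably improves recovery of planted
structure.

**Prediction flow.** A curated known-regulation store is consulted
first (exact key match under the configured directionality; no
reverse-orientation fallback — a directed activation A→B says nothing
about B→A). On a miss, the interaction is featurized; if it contains
no significant pair the result is the explicit `no_feature` status
(never a silent zero vector), so coverage = 1 − no_feature fraction is
always reported. Otherwise the classifier's label, probability and the
contributing pairs (with ER and p) are emitted.

**Evaluation.** `crossvalidate` runs seeded stratified k-fold CV on
fixed feature vectors (identical folds for L1 vs L2 comparisons).
`crossvalidate_interactions` is the leakage-safe default workflow: ER
scoring and the feature index are recomputed inside every training
fold, so held-out labels never influence the features; a `leaky_er`
flag reproduces pooled-ER scoring for comparison. Held-out
`no_feature` interactions are excluded from the metrics and reported
through the coverage figure.

## Directionality and identifiers

Interactions are directed by default (source = regulator); an
undirected mode canonicalizes both interaction keys and term pairs by
sorting endpoints. Protein identifiers are opaque, case-sensitive,
whitespace-free strings; no identifier mapping is attempted. GO
annotations are used literally — no propagation through the ontology
graph — and in GAF input only the object symbol/ID and GO ID columns
are read; qualifiers including `NOT` are ignored (documented
limitation).

## Synthetic data generator

The generator builds the world the model assumes, so green tests
certify the machinery, not biology:

- **Proteins and annotations.** 500 proteins; 90% are annotated, the
  rest exercise the `no_feature` path. Each annotated protein carries
  exactly one *family* term — its principal functional class, the way a
  signaling protein is primarily a kinase, phosphatase, receptor,
  adaptor or ligand — drawn from 5 families with skewed prevalences
  (0.30/0.25/0.20/0.15/0.10), plus `Poisson(2)` background terms from
  the remaining 25-term vocabulary (mean 3 annotations overall). Two
  namespaces (`go`, `domain`) are generated with the same structure.
- **Signal.** Sign effects live on family *pairs*: 10 planted cells of
  the 5×5 family grid, five at +3 (activation) and five at −3
  (inhibition) on the logit scale. Each interaction (uniform random
  ordered pair of distinct proteins, ~2000 of them) has
  `P(activation) = logistic(log 4 + Σ planted effects present)`;
  labels are Bernoulli draws. The base rate log 4 ≈ +1.386 encodes the
  ~4:1 activation:inhibition imbalance curated sets show.
- **Why families and this wiring.** Families are mutually exclusive
  within a protein, so an interaction carries exactly one family pair —
  annotation co-occurrence cannot smear planted signal onto unrelated
  terms. The planted cells are arranged so every family's row- and
  column-wise *expected* sign mixture is nearly neutral: a protein's
  class alone says almost nothing about sign, only the class pair does
  — which is precisely the premise of pair-based scoring. Activation
  cells sit on the more prevalent family combinations, consistent with
  activation dominating curated pathway data; this gives activation
  pairs the larger carrier mass. Under this design the hypergeometric
  screen recovers all ten planted pairs at the default α while
  admitting only a handful of borderline background pairs, and the L1
  support concentrates on the planted cells.
- **What it does not emulate.** Real GO DAG structure, correlated
  multi-domain architectures, study bias in annotation depth,
  multi-species conservation, and protein-complex confounding. A green
  recovery test therefore establishes correctness of scoring, feature
  construction, selection and prediction — not expected performance on
  real proteomes.

Everything is reproducible from one integer seed; the fixture bundle
(two annotation TSVs, a labeled interaction TSV, a planted-truth TSV
and a JSON manifest holding the config) regenerates byte-identically
from the manifest.

## Numerical choices and edge cases

- Hypergeometric tails: log-space summation over the support; the
  ER ≥ 1 branch decision uses exact rationals, immune to float
  rounding at ER = 1.
- Solver: scikit-learn saga, `C = 1/λ`, seeded; default stopping
  tolerance 1e-6 (1e-4 inside λ selection, where only an accuracy
  estimate is needed); iteration cap raises an explicit error instead
  of returning a silently unconverged model. λ = 0 uses unpenalized
  L-BFGS.
- Degenerate inputs: single-class training data returns the smoothed
  class-prior model (zero coefficients, intercept = logit of the
  add-½ prior) rather than failing; empty training data errors.
- Duplicate edges: first occurrence wins, deterministically, both in
  dataset hygiene and in the known store.
- Determinism: score tables are sorted by (q, p, pair); the feature
  index is lexicographic; ER-matrix clustering (scipy average linkage,
  Euclidean) operates on lexicographically pre-sorted terms so leaf
  orders are reproducible; repeated batch runs are byte-identical.
- `no_feature` is a distinguished singleton, not an empty vector, so
  the zero vector (possible only for an interaction whose indexed
  pairs all have ER 0) can never be confused with "cannot predict".

## Known limitations

- Coverage: only interactions containing at least one significant pair
  are predictable; on the default synthetic world that is roughly half
  the edges, and the no-feature rate is reported rather than hidden.
- ER features are computed from training data; for very rare pairs the
  ratio is noisy and survives the screen only with strong imbalance.
- The GO/domain models are deliberately separate; no combined model is
  offered.
- The CLI covers the standard flows with flags only; there is no
  config-file mirror.
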