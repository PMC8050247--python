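# Methods

## Data model

All inputs are strictly binary feature-by-sample matrices: entry (t, j) is 1
iff molecular feature *t* was detected in sample *j*. Feature extraction
(spectral library search, MS/MS clustering) is upstream of this package and
out of scope; binarization is taken as given. Missing values do not exist in
this representation — absence of a detection is a 0, and the readers reject
anything that is not 0 or 1, naming the offending feature and sample.
Feature IDs match by exact string equality; there is no mass-tolerance
matching. Two on-disk dialects are supported: dense TSV (feature rows ×
sample columns, matching common bucket-table exports) and MatrixMarket
coordinate files with ID sidecars for repository-scale sparse matrices.

## Balanced loss

Both models weight each term of their loss by the inverse multiplicity of
its class. For classification, sample *t* with label *y_t* gets weight
`1/b_t` where `b_t` is the number of training samples labelled *y_t*; for
decomposition, feature row *t* gets weight `1/b_t` where `b_t` counts the
entries of the query vector `c` equal to `c_t`. In both cases every class
contributes exactly one unit of loss mass. Two consequences are used as
exact numerical checks:

* with both classes present, the decomposition objective at `x = 0` equals
  `2 ln 2` (each of the two unit-mass classes contributes `ln 2` when every
  predicted probability is 1/2);
* the objective value at any fixed parameter point is invariant under
  duplication of a class's samples, because the weights renormalize.

## Classification

One-vs-rest penalized logistic regression with the per-sample balanced
weights applied inside each binary subproblem. The objective per class is
`Σ_t w_t L_t + s · P(β)` with `P` either `‖β‖₁` or `½‖β‖₂²`. The
subproblems are solved by scikit-learn's liblinear backend (mapping
`C = 1/s`); a multinomial softmax scheme (saga) is available behind a flag
but the one-vs-rest default keeps one interpretable coefficient vector per
class. liblinear reaches the penalized optimum deterministically at
tolerance 1e-8, which is what makes retraining bit-reproducible.

Choices that were genuinely open:

* **Intercept** — included, as in standard logistic regression practice.
  liblinear penalizes the intercept through its bias-augmentation trick;
  `intercept_scaling = 10` makes that extra penalty negligible.
* **Penalty strength** — no canonical value exists for this loss scale. The
  default (`strength="auto"`) runs a stratified 3-fold cross-validation over
  a geometric grid `1e-4 … 1` (the balanced loss has total mass ≤ 2, so
  strengths near or above 1 zero the model out), scored by *balanced*
  accuracy for consistency with the balanced loss; ties prefer the larger
  strength, i.e. the sparser model. Any positive float overrides it.
* **Tie-breaks** — prediction takes the first class in sorted vocabulary
  order among equal scores; biomarker ranking orders by descending
  |coefficient| then lexicographic feature ID. Both purely for determinism.

### Biomarker audit and artifact removal

The ranked coefficient table is the interpretability surface. Features known
to be internal standards (from the metadata's dataset→standard map) are
flagged `suspected_artifact`; flagging is semi-automatic by design — the
package never deletes a feature on its own, because no reliable automatic
rule distinguishes a protocol artifact from a genuine biomarker. Removal
happens only through an explicit blocklist: `remove_and_retrain` drops the
listed features (unknown IDs warn rather than fail, so one blocklist can
serve many matrices) and refits with identical penalty, strength, tolerance
and seed. An empty blocklist reproduces the original fit bit-for-bit.

## Decomposition

`min_x Σ_t w_t · CE(c_t, σ((Dx)_t)) + λ‖x‖₁` is convex; it is minimized by
FISTA (accelerated proximal gradient) with function-value adaptive restart,
step size `1/L` where `L = ¼‖diag(√w) D‖₂²` is the Lipschitz constant of the
weighted cross-entropy gradient. Convergence is declared when the relative
objective decrease stays below 1e-10 and the proximal-gradient residual
drops below 1e-7; non-convergence raises an error carrying the best iterate.
Probabilities inside the cross-entropy are clamped to `[1e-12, 1 − 1e-12]`.
There is no randomness anywhere in the solve, so repeated runs are
bit-identical.

* **Sign of x.** The objective is literally unconstrained, and the
  unconstrained minimizer can assign *negative* coefficients to absent
  ingredients (negative evidence also lowers cross-entropy on the 0-class).
  Selection therefore ranks by *signed* coefficient descending — large
  positive means present. A nonnegativity-constrained mode (`nonneg=True`),
  matching the abundance interpretation, changes the proximal step to
  `max(v − tλ, 0)` and is exposed throughout.
* **Numerical zero.** A coefficient counts as non-zero when
  `|x_i| > 1e-6 · max(1, ‖x‖_∞)`.
* **λ search.** `λ_max = ‖∇CE(0)‖_∞` (the standard L1 optimality condition
  at the origin) gives the smallest penalty with an all-zero solution. The
  path starts there and descends geometrically (factor 0.8) with warm
  starts until the non-zero count reaches the target *k*; if the count jumps
  past *k*, geometric-midpoint bisection (≤ 60 steps) searches the bracket.
  Warm starts only affect speed — the objective is convex. When no penalty
  attains exactly *k* (disjoint supports can activate in groups), the result
  falls back to the visited solution with the smallest count ≥ k, ranked and
  truncated to *k*, and is flagged `fallback`. Every visited
  `(λ, count)` pair is recorded in `path_log`.
* **Degenerate queries.** An all-zero or all-one `c` has a single value
  class (weight mass 1, not 2) and carries no contrast to decompose; such
  inputs short-circuit to `x = 0` with an empty selection and a `degenerate`
  flag rather than running the path. (For an all-zero `c` the unconstrained
  objective would otherwise be minimized by arbitrarily negative
  coefficients, which has no compositional reading.)

### Independent check

`metmix.validation.grid_search_minimum` minimizes the same objective by
exhaustive enumeration over a regular grid (default `[-3, 3]^d`, step 0.05),
sharing no code with the FISTA path. It exploits the binary structure of
`D`: rows are grouped by their 0/1 pattern and, on a regular grid, each
pattern's linear score takes only `d·(m−1)+1` distinct values, so the d = 4
grid (121⁴ points) evaluates in seconds. The test suite requires the FISTA
objective to be within 1e-3 of the grid minimum on random small problems.

## Synthetic data

The generators emit miniatures of the structures the methods assume; their
defaults are the conditions under which all shipped results are computed.

* `make_library` — ingredient profiles with exactly `support_size` ones per
  column. A shared pool of `round(overlap · support_size)` features is
  present in every ingredient and the rest of each support is private, so
  every pairwise support intersection is exactly the pool (`overlap = 0`
  gives disjoint supports). This is deliberately simpler than real food
  chemistry; it provides a controlled identifiability stress, not a
  simulation of co-occurrence structure.
* `make_complex` — the union of `k` uniformly chosen ingredient columns,
  then independent Bernoulli noise: each 1 dropped with probability
  `dropout`, each 0 spuriously set with probability `spurious`. The
  benchmark conditions used by the tests and the acceptance script are a
  40-ingredient, 800-feature, support-20 library with `overlap = 0.2`,
  `dropout = 0.05`, `spurious = 0.02`, k = 5.
* `make_cohort` — Bernoulli background (default rate 0.05), per-class
  signal features (default 8 per class at penetrance 0.9), and optionally a
  protocol confounder: features present iff the sample belongs to one source
  dataset, which in training-style generation coincides with one class —
  an internal standard spiked under a single protocol. The shifted variant
  places the confounded dataset over a *different* class, the configuration
  in which a model that learned the artifact fails. Default cohort
  proportions keep the majority class above 90 % in the imbalance tests,
  mirroring repository-scale phenotype tables; the batch-effect story uses
  150/60 train and 100/50 shifted-test cohorts with 2 confounder features.

What passing on these fixtures does **not** show: robustness to correlated
noise, to intensity effects (the package is presence/absence only), to
incomplete reference libraries, or to mis-annotated training labels. The
noise model is independent Bernoulli per feature because nothing stronger is
implied by the union assumption; rates are exposed so harsher regimes can be
probed.

## Problem sizes

The shipped experiments run at desk scale — libraries of 40 ingredients ×
800 features, cohorts of ~200 samples × 200 features, 20 + 50 decomposition
runs, grid enumeration up to d = 4 — chosen so the entire suite and the
acceptance script each complete in well under a minute while still
exercising every code path at sizes where the statistical contrasts (e.g.
recovered-overlap vs the `k·m/n` null) are unambiguous.

## Known limitations

* Abundances `x` are ordinal evidence, not calibrated proportions.
* The union assumption ignores reactions during preparation (molecules
  created or destroyed), a real source of discrepancy in food data.
* The λ-path fallback can return more than `k` active coefficients
  truncated to `k`; the `fallback` flag marks those results.
* One-vs-rest scores are not calibrated probabilities across classes.
* Batch-artifact detection remains human-in-the-loop: the package surfaces
  candidates and retrains after an explicit blocklist, by design.
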