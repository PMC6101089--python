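# Methods

## Model

The package treats a partially observed binary association table — microbes
in rows, diseases in columns, entries +1 (validated association), −1
(observed non-association) or unknown — as a one-bit observation of an
underlying real-valued low-rank matrix **X**. The observation model is

    a_ij = +1  if  x_ij + z_ij ≥ 0,   a_ij = −1 otherwise,
    z_ij ~ N(0, σ²) i.i.d.,

equivalently `P(a_ij = +1) = Φ(x_ij / σ)` with Φ the standard normal CDF: a
probit link. The observed index set Ω is assumed to arise from p·q
independent Bernoulli trials with success probability m/(pq) (a binomial
model for |Ω|).

**X** is recovered by maximizing the probit log-likelihood over Ω,

    F(X) = Σ_{(i,j)∈Ω} log Φ(a_ij · x_ij / σ),

subject to the nuclear-norm constraint ‖X‖\* ≤ τ = √(r·p·q), the convex
surrogate for a rank-r budget. The recovered entries x̂_ij are the
prediction scores; because AUC is invariant under strictly monotone
transforms, ranking by x̂_ij and ranking by Φ(x̂_ij/σ) are equivalent.

`F` is concave, so the negated likelihood over the nuclear ball is a smooth
convex problem with a unique optimal objective value. Internally everything
is minimization-form (−F and its gradient); the public likelihood API
reports the non-positive log-likelihood.

## Optimization

The solver is a nonmonotone spectral projected gradient (SPG) method of the
classic projected-point-then-backtrack variant: at each iterate the
Barzilai–Borwein step `α = ⟨s,s⟩/⟨s,y⟩` (clamped to `[1e-10, 1e10]`;
`α = α_max` on nonpositive curvature) is projected to produce the feasible
direction `d = P(x − αg) − x`, and a backtracking search along `x + λd`
accepts the first `λ` satisfying the nonmonotone Armijo condition against
the maximum of the last 10 objective values with sufficient-decrease
parameter `γ = 1e-4`. Backtracking uses safeguarded quadratic interpolation
restricted to `[0.1λ, 0.9λ]`. Because each trial point is a convex
combination of two feasible points, every iterate is feasible. Stopping is
on the unit-step projected-gradient residual `‖P(X − g) − X‖_F ≤ 1e-6`
(default), with a 300-iteration cap. Initialization is the zero matrix,
which is feasible for any τ > 0 and makes the fit fully deterministic. If no
step above `λ = 1e-16` satisfies the acceptance condition the solver stops
at the current iterate rather than accept an invalid step. All these solver
defaults are this package's choices, recorded in every `SolveReport`.

The projection onto `{X : ‖X‖* ≤ τ}` is singular-value soft-thresholding:
after a full SVD (problem sizes here are a few hundred rows at most, so a
dense SVD is the right tool), the shrink level λ is the smallest value with
`Σ max(s_i − λ, 0) ≤ τ`, found exactly by sorted-prefix water-filling — the
same closed form as ℓ1-ball projection — rather than by bisection, so the
projection has no tolerance knob. Singular values below 1e-12 are zeroed
first as numerical rank noise.

### Numerical care

`log Φ` and the gradient factor `φ/Φ` are evaluated through
`scipy.special.log_ndtr` (and `exp(log φ − log Φ)`), never through a naive
`log(Φ(x))`, because cross-validation routinely drives margins to
`x/σ < −8` where the naive form underflows to −inf. The analytic gradient is

    ∂F/∂x_ij = (a_ij/σ) · φ(x_ij/σ) / Φ(a_ij·x_ij/σ)  on Ω,  0 elsewhere.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| σ | probit noise scale (a standard deviation; the link divides by it) | 0.2 | the grid-search optimum on the motivating microbe–disease data |
| r | rank budget; τ = √(r·p·q) | ⌈r_max/3⌉ via ratio 1/3, r_max = min(p, q) | same grid-search optimum |
| unknown-pair policy | unlisted pairs observed −1 vs unknown | `as_negative` | association databases record only positives; ranking against all non-positives matches the standard link-prediction protocol. The alternative is one flag away. |
| SVD-baseline fill | value imputed at unknown cells before truncated SVD | 0 | midpoint of ±1; −1 available |

Note σ and the scale of **X** are jointly unidentifiable from one-bit data
(scaling both leaves the label distribution unchanged); σ is best read as a
regularization-strength dial relative to τ rather than a consistently
estimable noise level. This is also why grid search on synthetic data need
not select the generative σ even when ranking performance is excellent.

## Evaluation protocol

Two blinding schemes:

* `all_observed` k-fold: all observed entries are partitioned (sizes within
  1); each fold is refit without its test entries and the test entries are
  scored with their true labels.
* `positives_only` (LOOCV default): each blinded positive is scored against
  the candidate set of all pairs never observed as positive, and all folds
  are pooled into a single score/label vector producing one ROC and one PR
  curve. Per-fold metrics and their means are reported alongside, since
  defining "final performance" as a per-round average is the other common
  convention; for single-positive LOOCV folds the pooled curve is the
  meaningful one.

AUC is the Mann–Whitney statistic with midranks (exactly the trapezoidal
ROC area). AUPR is non-interpolated average precision with tied scores
grouped at one threshold; trapezoidal PR integration is deliberately
avoided as it overestimates. Both are implemented standalone and verified
against quadratic-time brute-force oracles and scikit-learn in the tests.

Grid search over (σ, rank ratio) evaluates every cell on the same folds
(drawn once from the CV seed) so fold noise cancels from the comparison,
selects by pooled AUPR — chosen over fold-averaged AUPR because it remains
well-defined for single-positive folds — and breaks ties toward smaller r,
then smaller σ. AUPR rather than AUC is the criterion because positives are
heavily outnumbered in association screening.

## Synthetic data: what it does and does not emulate

`simulate` draws `X_true = L Rᵀ` (i.i.d. Gaussian factors scaled to a target
entry standard deviation), adds Gaussian noise, thresholds at zero, and
samples Ω entrywise-independently — exactly the generative assumptions
above, including the binomial Ω model (cells are Bernoulli-observed rather
than sampling exactly m cells). Passing recovery tests on this data shows
the estimator is consistent with its own model; it does not show robustness
to features of real association data the generator omits: extreme
row/column degree skew (most microbes have a single known disease), biased
(non-uniform-random) observation, and label noise that is not Gaussian in a
latent score. The fully-observed synthetic matrices are also far denser in
positives (~50%) than curated databases (~4%), which inflates AUPR relative
to what sparse real data yields.

Benchmark problem sizes used by the test suite and the acceptance script
(60×30 rank 3 for recovery, 40×20 for LOOCV, 30×15 for tuning, ≤100k draws
for calibration) are chosen to exercise every code path at sub-minute cost;
recovery quality at these sizes is already stable across seeds.

## Degenerate inputs and edge rules

* Empty Ω → error ("nothing to fit"); a CV fold that leaves no training
  positives → error.
* Input label `0` is refused: ambiguous between "negative" and "unknown".
* Duplicate pairs with conflicting labels → error naming the line;
  consistent duplicates collapse to one record.
* Score-table ties are broken by (row, col) index ascending; metric ties use
  midranks (AUC) and grouped thresholds (PR); grid-search ties prefer the
  simpler model.
* `tol = ∞` returns the start point after zero iterations.

## Known limitations

* No logit or other links; the model is probit-only.
* No similarity/feature integration and no cold-start prediction for a
  microbe or disease with no known association (a zero row/column gets a
  zero score row from the zero-initialized fit).
* Full dense SVD per iteration bounds practical problem size to a few
  thousand rows/columns.
* The two comparator network methods from the microbe–disease literature
  (KATZ-index and ranking-KNN approaches) are out of scope; the only
  built-in comparator is the truncated-SVD baseline.
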