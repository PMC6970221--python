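# Methods

This note records the models implemented in `crosslatent`, the numerical
and design choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Models

### Sparse PLS

One latent effect is the penalized rank-one decomposition of the
cross-product matrix M = XᵀY of two column-centered views:

    max_{u,v} uᵀ M v   s.t. ‖u‖₂ = 1, ‖u‖₁ ≤ c_u,  ‖v‖₂ = 1, ‖v‖₁ ≤ c_v.

This is the form in which an elastic-net-constrained sparse CCA with
identity within-view covariances reduces to sparse PLS: the unit-sphere
constraint plays the role of the L2 (ridge) penalty, the L1 ball induces
exact zeros, and no separate ridge weight is exposed. Each alternating
step maximizes the objective in one weight vector with the other held
fixed; the maximizer is soft-threshold-then-normalize,
w = S(a, Δ)/‖S(a, Δ)‖₂ with a = Mv (or Mᵀu), using the smallest Δ ≥ 0
that meets the L1 budget.

Numerical choices:

- **Threshold solve.** Bisection on Δ (tolerance 1e−8, cap 200 iterations)
  brackets the active set; within a fixed active set the budget equation
  ‖S‖₁ = c‖S‖₂ is a quadratic in Δ and is solved in closed form. The
  closed-form finish matters: with bisection alone the alternating
  objective can decrease at the ~1e−9 level, while the implemented update
  is monotone to machine precision.
- **Unreachable budgets.** The achieved L1 norm can drop no lower than
  √m, where m counts entries tied at the maximal magnitude. If the budget
  lies below that (in particular c = 1 with ties), the one-hot vector at
  the lowest-index maximum is returned.
- **Budgets above √d** are accepted and simply inactive (the constraint
  cannot bind on the unit sphere).
- **Initialization** is the leading right singular vector of M —
  deterministic, so repeated fits inside the resampling loops are
  identical; no random restarts.
- **Convergence** when max(‖u−u′‖₂, ‖v−v′‖₂) < 1e−6 (default), cap 500
  iterations; non-convergence returns the current iterate flagged
  `converged=False` with a warning rather than failing, since inner-loop
  fits at extreme sparsity occasionally cycle between near-equivalent
  supports.
- **Sign convention.** v is flipped if needed so the training Pearson
  correlation of (Xu, Yv) is nonnegative; validation and holdout
  correlations are then *signed*, which is what makes the one-sided
  permutation test coherent.

### Regularized kernel CCA

With linear kernels K_x = XXᵀ, K_y = YYᵀ built from explicitly centered
data, one effect solves

    max_{α,β} αᵀ K_x K_y β
    s.t. (1−κ_x) αᵀK_x²α + κ_x αᵀK_xα = 1,  (analogously for y).

κ = 0 normalizes the score variance (classical CCA, maximal correlation);
κ = 1 normalizes the primal weight norm ‖Xᵀα‖₂ (PLS, maximal covariance);
intermediate values interpolate smoothly. Primal weights are recovered as
w = Xᵀα/‖Xᵀα‖₂, so downstream scoring, deflation, and reporting are
identical for both model families.

Numerical choices:

- Each kernel is eigendecomposed once and rank-truncated at a relative
  eigenvalue of 1e−10; in that basis both constraints are diagonal and the
  problem reduces to the leading singular pair of a small matrix. This is
  deterministic and exact at the sample sizes the framework targets; no
  incomplete-Cholesky approximation is used. The eigenbases do not depend
  on κ, so they are computed once per training split and reused across the
  whole κ grid.
- A jitter (default 1e−9 · trace(K)/n) is added to the constraint
  diagonals for solvability when κ → 0 meets a rank-deficient kernel.
- Sign convention: the largest-magnitude entry of α is made positive, and
  the v-weight is flipped if needed so the training score correlation is
  nonnegative, as for SPLS.
- Only the leading eigenpair is used per effect; successive effects come
  from projection deflation in primal space with kernels recomputed from
  the deflated data, mirroring the SPLS loop rather than taking lower
  eigenpairs. The constraint normalization above is a reconstruction of
  the regularized-CCA family this implementation extends; it is chosen so
  the two endpoints are exactly classical CCA and PLS, which the tests
  verify against independent oracles.

## The multiple-holdout framework

- **Splits.** n samples are split `n_outer_splits` times (default 10) into
  optimization/holdout sets (default 80/20); each optimization set is
  split `n_inner_splits` times (default 50) into training/validation sets
  (default 80/20, mirroring the outer ratio — the inner fraction is a
  package choice). Inner splits are independent random subsamples, not a
  partitioned cross-validation. All index draws descend from the single
  master seed.
- **Preprocessing.** Confounds are removed by per-feature OLS on
  [1, confounds] fitted on each outer optimization set and applied to the
  corresponding holdout rows (a `global_confound_removal` switch
  reproduces the simpler whole-dataset residualization, at the cost of
  leaking holdout rows into the confound fit). Mean-centering is always
  on; unit-variance scaling is optional and off by default. Inside the
  inner loop only the centering is refit on each training subsample: the
  optimization-set matrix is already residualized (and possibly deflated),
  and refitting the confound regression on residualized rows would be a
  near no-op that complicates the deflation bookkeeping.
- **Grid search and selection.** Every hyperparameter cell is fit on each
  inner training set; validation out-of-sample correlation and the
  stability of the fitted weights across inner fits are recorded. SPLS
  stability is the chance-corrected pairwise support overlap
  (|A∩B| − |A||B|/d)/(min(|A|,|B|) − |A||B|/d) averaged over pairs and
  views (pairs with empty or full supports contribute 0); KCCA stability
  is the mean absolute pairwise Pearson correlation of the weight
  vectors. Cells are ranked descending on mean validation correlation and
  on stability; the minimal rank sum wins, ties going first to the higher
  validation correlation and then to the more regularized cell (smaller
  L1 budget, larger κ). Cells with degenerate fits in more than half the
  inner splits are excluded. The chance-corrected overlap and the
  rank-sum combination are deliberately isolated behind single functions
  (`corrected_overlap`, `select_hyperparams`) so alternative formulations
  can be swapped in.
- **Inference.** The selected cell is refit on the full optimization set
  and evaluated on the holdout set: the observed holdout correlation is
  compared with a null distribution obtained by permuting the holdout
  rows of the y view (permuting one view suffices to break the pairing);
  p = (1 + #{r_perm ≥ r_obs})/(n_permutations + 1), one-sided under the
  train-positive sign convention. Across outer splits the default verdict
  is Bonferroni on the minimum p — significant iff min p ≤ α/n_splits,
  with the non-strict comparison because permutation p-values are
  discrete and their smallest achievable value can coincide with the
  threshold — plus a reported count of splits with p < α; a majority rule
  is available. The reported "best split" minimizes the rank sum of
  holdout correlation and stability, ties to the higher correlation.
- **Deflation.** A significant effect is removed from every split by
  projection, X ← X(I − uuᵀ) and Y ← Y(I − vvᵀ), using that split's
  optimization-set weights for its holdout rows as well, which preserves
  the leakage guarantee; the loop continues to the next effect until the
  first non-significant one (returned, flagged) or `max_effects`.
- **Failure handling.** A split whose grid search or fit degenerates is
  dropped from the across-split decision with a warning as long as at
  least 80% of splits (minimum 2) survive; otherwise the run aborts.

## Synthetic data

The generator draws latent factors z_k ~ N(0,1) and builds
X = Σ_k s_k z_k u_kᵀ + γ·F·G_x + E_x (Y analogously), with sparse unit
loading vectors whose supports are disjoint across effects within a view,
equal ±1 magnitudes on the support before normalization (a decaying-
magnitude option stresses the sparsity path), confound values F with
random unit loading rows, and iid Gaussian noise. Strictly decreasing
effect strengths make the extraction order identifiable. A Student-t
option exists for heavy-tailed latents.

What it emulates: the cross-view low-rank-plus-noise structure, sparse
per-view loadings, shared confounds, and exact reproducibility from one
seed. What it does not: spatial autocorrelation of imaging features,
bounded/ordinal questionnaire items, site/batch structure beyond generic
confound columns, or missing data. Passing recovery tests therefore shows
the framework's statistical machinery works under a well-specified linear
model — not that real imaging or questionnaire data meet its assumptions.

## Validation problem sizes

The acceptance script and tests exercise: oracle equivalences on 20×6/20×4
(SPLS vs SVD, 50 instances) and n=100, p=q=4 (KCCA vs classical CCA and
PLS); L1 projection against brute-force enumeration (100 random vectors, a
coarse 1e4-point bracket refined by a second 1e4-point pass); permutation
calibration with 500 independent-view replicates at 199 permutations;
whole-framework null calibration on 200 noise datasets of n=60, p=q=8
with 5 outer × 10 inner splits, a 3×3 grid, and 99 permutations; planted-
effect recovery at n=500, p=q=100, two effects with 10% disjoint supports
and strengths 3 and 2 under unit noise, run with 5 outer × 10 inner
splits, a 5-point log-spaced budget grid per view spanning [1, √100], and
199 permutations; and SPLS/KCCA congruence at n=300, p=q=30. These sizes
are the package's validation conditions, chosen so the whole battery runs
on a single CPU in a few minutes.

## Known limitations

- **Residual effects after deflation.** Deflation removes the *estimated*
  direction; when a strong effect is estimated with error, its remnant can
  stay weakly detectable in the next round (see the worked example in the
  README). This is a property of deflation-based extraction generally, not
  of this implementation; interpreting late effects warrants caution.
- **Support recovery vs. budget discretization.** The rank-sum criterion
  only weakly penalizes budgets just above the true L1 radius, where many
  tiny spurious weights enter: weight cosines stay high but support F1 can
  collapse. Support-based interpretation benefits from a grid that
  actually brackets plausible sparsity levels; the stability criterion
  tends to prefer the reliably detectable *sub*-support, so a slightly
  conservative (sparser) selection is typical.
- With a single outer split the across-split decision degenerates to one
  permutation test; the framework's robustness claims need several splits.
- Only linear kernels are implemented for KCCA (the abstraction accepts a
  precomputed kernel, so a nonlinear kernel is a drop-in); group-sparsity
  penalties and more than two views are out of scope.
- Confound handling is linear OLS; categorical confounds must be supplied
  as indicator columns.
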