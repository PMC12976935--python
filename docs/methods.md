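# Methods

## The model

`funclust` learns *functional groups*: a partition of `n` community
features (species, ASVs, genera, or gene modules) into a small number
`K` of groups whose summed abundances predict a measured community
function. For a sample with abundance row `x ∈ R^n` and function row
`f ∈ R^m` the model computes

1. **gate** (optional): `x_g = γ ⊙ x` with `γ = sigmoid(ℓ)`,
   `ℓ ∈ R^n` learnable;
2. **aggregation**: `g = x_g C`, where `C ∈ R^{n×K}` is a clustering
   matrix with approximately one-hot rows;
3. **map**: `f̂ = NN_θ(g)`, a small fully connected network.

The discrete assignment is relaxed with the Gumbel-softmax trick. Each
feature carries a row of logits whose row-softmax is an assignment
probability matrix `P`; at every training step a clustering is sampled as

    C = row_softmax((Γ + log P) / τ),   Γ_ij ~ Gumbel(0, 1) i.i.d.

As the temperature `τ → 0` the rows of `C` approach one-hot indicators of
categories drawn from the rows of `P` (the Gumbel-max property), while for
finite `τ` the sample stays differentiable in the logits. We use the
relaxed sample directly (no straight-through hard-argmax estimator): at the
annealed floor `τ = 0.1` rows are near-one-hot, which is the regime the
downstream map is meant to see. `log P` is computed as a log-softmax of the
logits directly, never through a materialized `P`.

The loss is the batch mean of squared prediction errors,
`L = (1/B) Σ_i ||f_i − f̂_i||²`, plus `β ||γ||₁` when gating is enabled.
Since `γ ∈ (0,1)` the L1 term is simply `β Σ γ_i`, a constant pull toward
closed gates that only features with predictive value resist.

All forward and backward passes are hand-derived numpy; the gradients are
verified against central finite differences (to better than 1e-7 relative
in practice; the test bound is 1e-4). One Gumbel matrix is drawn per
iteration and shared by the whole batch.

## Training protocol

- **Splits.** Each ensemble member gets an independent uniformly random
  train/test split (`train_fraction` default 0.8, `round(0.8·N)` training
  samples). Member split and initialisation seeds derive from the master
  seed through a `SeedSequence`, so the ensemble is reproducible and
  independent of training order.
- **Optimization.** Full-batch Adam (the datasets this method targets have
  at most a few thousand samples); plain gradient descent is available via
  `optimizer: sgd`. The temperature anneals per iteration as
  `τ(t) = max(τ_min, τ_max · exp(−r_τ t))`, defaults 1.0 → 0.1.
- **Early stopping.** The held-out MSE is evaluated every `eval_every`
  iterations (default 2) using the *deterministic argmax clustering* — the
  same clustering the consensus step later reads off — with no gate
  penalty. Training stops when this has not improved for
  `early_stop_patience` iterations or at `max_iters`; the best-held-out
  parameters are kept. Using the pure MSE (not the gated loss) for early
  stopping keeps the criterion comparable across β values.
- **Grid search.** `grid_search` trains a full ensemble per grid point over
  (η, r_τ, and optionally β) and selects the lowest median held-out MSE.
- **Cluster-number scan.** `scan_ncluster` repeats ensemble training over a
  range of K and reports per-member and median held-out losses together
  with the function variance — the level a constant predictor attains, and
  approximately where the degenerate K = 1 model lands.

## Consensus extraction

Members are ranked by held-out pooled R² and the top fraction kept
(default 25% for the benchmark studies; `top_fraction` configurable).
Group labels are aligned across members by sorting groups on mean group
abundance over the full dataset (or on correlation with a designated
function column); exact key ties fall back to maximal-overlap assignment
against the top-ranked member. Each feature then takes its modal argmax
assignment; vote ties break toward the larger mean assignment probability,
then the lower group index. With gating, a feature is active iff
`γ ≥ 0.5` (the sigmoid midpoint) in a strict majority of the *selected*
members; counting over the full ensemble instead is available via
`consensus(members=...)` on a different selection.

## Synthetic benchmark

Twelve species in three hidden groups of four consecutive species each;
per-species abundances are independent uniform(0, 1); 500 samples. The
scalar function is linear in the group sums `G_1..G_3` with coefficients
that switch between three regimes by the median conditions on `G_1, G_2`:

- `a = (0.1, 1, 1)` when `G1 > med(G1)` and `G2 > med(G2)`,
- `a = (1, −0.5, −0.1)` when `G1 > med(G1)` and `G2 ≤ med(G2)`,
- `a = (−1, 0.1, −1)` when `G1 ≤ med(G1)`,

so each regime is exactly linear but the global map is not. Boundary ties
join the "greater" branch; under the continuous abundance law they have
probability zero, the rule only makes generation deterministic. Optional
function-irrelevant species are appended for gating studies (never entering
`f`, labelled group 0 in the truth), and optional additive Gaussian noise
on `f` supports robustness studies.

What the generator does *not* emulate: compositional (relative-abundance)
constraints, species-species correlations, overdispersed count noise,
measurement error on abundances, and more groups than three. Passing the
recovery studies therefore demonstrates the machinery — gradient flow from
function to clustering, ensemble consensus, gating — under the assumed
statistical structure, not robustness to the full messiness of field data.

## Recovery score

Group recovery is scored per truth group as the best
intersection-over-union against any predicted group, averaged over truth
groups. (A displayed variant with `|i| + |j|` in the denominator — under
which perfect recovery scores 0.5 — is available via
`sum_denominator=True`; intersection-over-union is the default because a
perfect match should score 1.) When gating was used, inactive features are
scored as their own predicted "irrelevant" class against the truth's, and
removed from the real groups.

## Baselines

- **Model I**: average-linkage hierarchical clustering of features on the
  correlation distance `1 − r` (function-blind), then ordinary least
  squares from group sums to the function. Constant features get zero
  correlation.
- **Model II**: the same frozen clustering with the neural map.
- **Model III**: simulated annealing over hard assignments (single-feature
  reassignment moves, geometric temperature 1 → 1e-3, default 20,000 moves
  and 5 restarts) minimizing the training MSE of the best linear map.
- **PCA + linear**: principal components of the training abundances,
  linear regression of the function on the projections.

All baselines take the same split as the main method for paired
comparison.

## Consumer-resource model

Two aggregate biomasses grow on nitrate `A` and carbon `C` with Monod
saturation (yields `γ_i` per mM nitrate, rates `r_i` mM/day, relative
carbon consumption `r_C`, affinities `K_A = K_C = 1e-3` mM):

    dx_i/dt = γ_i r_i x_i · A/(A+K_A) · C/(C+K_C)
    dA/dt  = −(r_1 x_1 + r_2 x_2) · A/(A+K_A)
    dC/dt  = −(x_1 + r_C x_2) · C/(C+K_C)

While both resources last, growth and depletion are near-exponential; once
carbon runs out at the depletion time `t*`, biomass freezes and nitrate
declines linearly (`t* = 0` reproduces the growth-inhibited,
chloramphenicol-style linear regime). The piecewise-analytic solution
replaces the ODE in the fitting loop, with `t*` substituting for the
unobservable initial carbon; at the default affinities it agrees with
adaptive LSODA integration to ~0.2% on `A(t)`, and the agreement improves
monotonically as the affinities shrink.

**Fitting.** `γ_1, γ_2` are global across samples and found by grid search
(20 log-spaced points on [0.05, 5] by default); `r_C` is fixed at 1
(configurable); `(r_1, r_2, t*)` vary per sample and are found by bounded
trust-region least squares on residuals combining the nitrate series and
the two endpoint biomasses, each block scaled by its dataset-wide standard
deviation. The first solve at each sample uses a data-driven start (the
early nitrate slope sets the total rate) plus random restarts; subsequent
grid points warm-start from the neighbouring solution, with the data-driven
start retained as a hedge — this continuation is what makes the repeated
fits of the null-model comparison affordable. Samples with `x_2(0) = 0`
cannot identify `r_2`; it is reported as NaN and listed in
`unidentifiable_r2`.

The noiseless recovery study generates data with yields **on** the search
grid (the generator defaults are the grid points nearest 0.5 and 1.9):
with off-grid yields the grid search is structurally unable to return the
truth and neighbouring yields trade off against the per-sample rates, so
the self-consistency check would measure the grid discretization rather
than the fitter.

**Null model.** A group is replaced by a random species set drawn from
outside it whose total initial abundance matches within 5% (greedy random
assembly with rejection, 10,000 attempts). The same fitting procedure runs
on each null grouping (a 6-point yield grid keeps 100 refits affordable;
relative error orderings are insensitive to this coarsening) and the
one-sided empirical p-value uses the add-one convention
`p = (1 + #{null ≤ true}) / (1 + n_null)`. As with the recovery study,
the packaged null study generates data with yields on its own search
grid: the comparison asks whether the *grouping* matters, which
presumes the fitted model class can represent the true dynamics.

## Study sizes and numerical choices

The packaged studies (tests, `scripts/acceptance.py`, examples) run the
12-species benchmark with a (32, 32) network, learning rate 1e-2,
annealing rate 5e-4, at most 9,000 iterations with patience 900, ensembles
of 12, and top-25% consensus. A map from three group abundances to a
scalar does not benefit from the larger (128, 128, 128) default, and the
slow annealing lets the assignment probabilities harden before early
stopping can fire; the library defaults keep the general-purpose values.
The Monte-Carlo baseline runs 8,000 moves × 3 restarts in the studies.

The nitrate-noise robustness study fits its 50 replicate incubations
jointly: yields are global across samples by the model's own assumption,
and it is that pooling which identifies them — with only a handful of
samples the yield profile is nearly flat and grid misselection leaks into
the recovered rates.

The argmax-frequency check of the Gumbel-max property uses a 2-feature
model: the property is per-row, and a small cell count keeps a joint
3-standard-error bound a sharp test instead of a multiple-comparison
lottery.

Other conventions: cluster logits initialise to zero (uniform assignment
probabilities — an unbiased starting clustering); gate logits initialise
at +2 (gates ~0.88 open, so the penalty must actively close a feature);
network weights are Glorot-scaled normals; function columns are z-scored
per column when `m > 1` (off for scalar targets; configurable); table
round-trips print floats with `%.17g` and parse them in round-trip mode so
read∘write is exact.

## Gating behaviour in practice

Because the gate multiplies abundances by a positive scalar and the
downstream network can rescale its inputs, the L1 penalty is structurally
minimized by shrinking a gate while the first-layer weights grow — so a
*relevant* feature's gate can drift below the 0.5 activity threshold
without losing predictive signal. Empirically on the gating benchmark the
gates of the two regime-setting groups stay open at the mildest grid
penalty (1e-4) while all function-irrelevant species close; the
low-leverage third group closes at every penalty, and at stronger
penalties group 2 closes as well — sometimes with *better* held-out MSE,
because a nearly-shut gate also damps the prediction noise injected by
Gumbel assignment resampling. The gating study therefore evaluates the
irrelevant-exclusion / regime-group-retention property at the mildest grid
penalty, reports the loss-selected penalty alongside, and checks that the
active count is non-increasing in β. Treat the active set as "features
the model could not do without at this sparsity pressure", not as a
complete list of functionally relevant taxa.

## Limitations

- Function noise hinders group identification; the benchmark's noise knob
  exists precisely to study that, and no claim is made about noisy-data
  recovery rates.
- Consensus majority voting assumes most selected members land near the
  same optimum; with badly chosen hyperparameters (too-fast annealing,
  large learning rates) members disagree and the agreement fractions
  reveal it.
- The consumer-resource fit assumes the two-phase analytic picture;
  dynamics with gradual carbon limitation (large `K_C`) or regrowth are
  outside its class.
- Yields are only identified up to the resolution of the search grid, and
  only when endpoint biomasses are measured.
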