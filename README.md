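# funclust

Function-informed soft clustering of microbial communities — and of any
other system whose members can be meaningfully aggregated by summation.

## The problem

Microbial communities carry out collective functions (metabolite
production, nitrate reduction, ...) that depend on the abundances of many
taxa. Interpreting such data calls for a drastic reduction: find a small
number of **functional groups** — sets of species, ASVs or gene modules —
whose *summed* abundances predict the measured function. Classical
clustering groups features by co-occurrence and never looks at the
function; regression looks at the function but keeps every feature as its
own variable. `funclust` does both at once: it learns the grouping and a
nonlinear structure-function map jointly, so gradient information flows
from prediction error back into the cluster assignment.

## The method

For abundances `x ∈ R^n` and measured function `f ∈ R^m`:

    g = (γ ⊙ x) C,          f̂ = NN_θ(g),
    C = row_softmax((Γ + log P)/τ),   Γ_ij ~ Gumbel(0,1)

`P` is a learned row-stochastic assignment-probability matrix; the
Gumbel-softmax sample `C` is an approximately one-hot clustering that
stays differentiable, with sharpness annealed via the temperature `τ`.
The optional gate `γ = sigmoid(ℓ)` with an L1 penalty `β‖γ‖₁` switches
irrelevant features off entirely, yielding sparse groups. Training
minimises `(1/B) Σ ‖f − f̂‖² + β‖γ‖₁` by full-batch Adam over an ensemble
of random train/test splits; a consensus grouping is distilled from the
top-performing members by majority vote after resolving the group-label
permutation ambiguity. See `docs/methods.md` for the full protocol.

The package also ships:

- a synthetic benchmark with known groups and a regime-switching (hence
  globally nonlinear) structure-function map;
- the baseline comparators: co-occurrence clustering + linear/neural map,
  Monte-Carlo function-informed clustering + linear map, PCA + linear
  regression;
- a recovery score (mean best intersection-over-union between truth and
  learned groups);
- a two-biomass consumer-resource model for nitrate dynamics (Monod
  kinetics on nitrate and carbon) with a piecewise-analytic solution,
  grid + least-squares parameter inference, and an abundance-matched
  null-model comparison that asks whether the learned groups are the
  *right* variables for the dynamics.

## Worked example

`examples/01_recover_groups.py` generates the benchmark (500 samples,
12 species in 3 hidden groups), trains an ensemble of six models and
extracts the consensus:

```
$ python examples/01_recover_groups.py
dataset: 500 samples x 12 species, scalar function
median held-out R^2 across members: 0.959
consensus labels: [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3]
true labels:      [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3]
total Jaccard vs truth: 1.000
A total Jaccard of 1.0 means every hidden group was recovered exactly
(group numbering is arbitrary; the score is permutation-invariant).
```

Every hidden group is recovered exactly (total Jaccard 1.0) and the
learned nonlinear map explains ~96% of held-out function variance, which
a linear map — even on the true groups — cannot
(`examples/03_baselines.py` prints R² 0.51 for the best linear
comparator).

The other examples cover sparse gating (`02`), the baseline comparison
(`03`), consumer-resource parameter recovery (`04`) and the null-model
comparison (`05`); each prints the numbers it computes and a line on what
they mean. A `funclust` command-line interface exposes the same pipeline
stages (`benchmark`, `train`, `scan`, `consensus`, `baselines`, `crm-fit`,
`crm-null`) for shell use.

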