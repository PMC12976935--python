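"""Synthetic benchmark with known functional groups.

Generates a community of ``n_species`` species partitioned into
``n_groups`` hidden groups. The scalar community function is linear in the
group abundances,

    f(x) = sum_i a_i * G_i(x),   G_i(x) = sum_{j in I_i} x_j,

but the coefficient vector ``a`` switches between three regimes depending on
whether the first two group abundances lie above or below their population
medians — emulating communities whose structure-function coupling shifts with
environment (e.g. pH). Globally f is therefore a nonlinear function of the
group abundances even though each regime is linear, which is exactly the
setting a nonlinear function-informed clustering should resolve and linear
or function-blind baselines should not.

Optionally ``n_irrelevant`` extra species are appended that never enter f;
they are the targets of the gating (sparsity) mechanism and are labelled
group 0 in the returned truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AbundanceMatrix, FunctionMatrix

__all__ = [
    "BenchmarkSpec",
    "RegimeCoefficients",
    "group_sums",
    "select_regime",
    "generate_benchmark",
]

IRRELEVANT_LABEL = 0


@dataclass
class RegimeCoefficients:
    """The three regime coefficient vectors (a^(1), a^(2), a^(3))."""

    a1: tuple = (0.1, 1.0, 1.0)
    a2: tuple = (1.0, -0.5, -0.1)
    a3: tuple = (-1.0, 0.1, -1.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3], dtype=float)


def _default_assignment(n_species: int, n_groups: int) -> np.ndarray:
    # 4 consecutive species per group with the 12/3 defaults
    return np.repeat(np.arange(1, n_groups + 1), int(np.ceil(n_species / n_groups)))[:n_species]


@dataclass
class BenchmarkSpec:
    n_species: int = 12
    n_groups: int = 3
    group_assignment: np.ndarray | None = None
    n_samples: int = 500
    n_irrelevant: int = 0
    noise_sd: float = 0.0
    abundance_law: str = "uniform"  # independent per-species uniform(0,1)
    seed: int = 0

    def __post_init__(self):
        if self.group_assignment is None:
            self.group_assignment = _default_assignment(self.n_species, self.n_groups)
        self.group_assignment = np.asarray(self.group_assignment, dtype=int)
        if self.group_assignment.size != self.n_species:
            raise ValueError("group_assignment length must equal n_species")
        present = set(self.group_assignment.tolist())
        if present != set(range(1, self.n_groups + 1)):
            raise ValueError("every group 1..n_groups must be non-empty")
        if self.n_samples < 1 or self.n_irrelevant < 0 or self.noise_sd < 0:
            raise ValueError("invalid benchmark sizes")
        if self.abundance_law != "uniform":
            raise ValueError(f"unknown abundance law {self.abundance_law!r}")


def group_sums(x: np.ndarray, assignment: np.ndarray, n_groups: int = 3) -> np.ndarray:
    """Group abundances G_i = sum of x over the species of group i.

    ``x`` may be a single row or a batch; irrelevant species (label 0) are
    ignored.
    """
    x = np.asarray(x, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    out = np.stack(
        [x[..., : assignment.size][..., assignment == g].sum(axis=-1) for g in range(1, n_groups + 1)],
        axis=-1,
    )
    return out


def select_regime(G: np.ndarray, medians: np.ndarray) -> int:
    """Regime index per the median conditions on G1 and G2.

    1 if G1 > med(G1) and G2 > med(G2); 2 if G1 > med(G1) and G2 <= med(G2);
    3 if G1 <= med(G1). Exact equality joins the "greater than" branch
    (measure-zero under continuous abundance laws; the tie rule only makes
    the boundary deterministic).
    """
    g1_high = G[0] >= medians[0]
    g2_high = G[1] >= medians[1]
    if g1_high and g2_high:
        return 1
    if g1_high:
        return 2
    return 3


def generate_benchmark(
    spec: BenchmarkSpec | None = None, coeffs: RegimeCoefficients | None = None
):
    """Generate (AbundanceMatrix, FunctionMatrix, truth dict).

    truth contains 'labels' (per-feature group, 0 = irrelevant), 'regimes'
    (per-sample regime index), 'medians' (of G1..G3 over the sample set) and
    'group_abundances'.
    """
    spec = spec or BenchmarkSpec()
    coeffs = coeffs or RegimeCoefficients()
    A = coeffs.as_array()
    if A.shape != (3, spec.n_groups):
        raise ValueError("coefficient vectors must have one entry per group")
    rng = np.random.default_rng(spec.seed)

    n_total = spec.n_species + spec.n_irrelevant
    X = rng.uniform(0.0, 1.0, size=(spec.n_samples, n_total))
    G = group_sums(X, spec.group_assignment, spec.n_groups)
    medians = np.median(G, axis=0)

    regimes = np.empty(spec.n_samples, dtype=int)
    f = np.empty(spec.n_samples)
    for i in range(spec.n_samples):
        r = select_regime(G[i], medians)
        regimes[i] = r
        f[i] = A[r - 1] @ G[i]
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)

    labels = np.concatenate(
        [spec.group_assignment, np.full(spec.n_irrelevant, IRRELEVANT_LABEL, dtype=int)]
    )
    sample_ids = [f"s{i:04d}" for i in range(spec.n_samples)]
    feature_ids = [f"sp{j:02d}" for j in range(n_total)]
    Xm = AbundanceMatrix(sample_ids=sample_ids, feature_ids=feature_ids, values=X)
    Fm = FunctionMatrix(sample_ids=sample_ids, function_names=["f"], values=f[:, None])
    truth = {
        "labels": labels,
        "regimes": regimes,
        "medians": medians,
        "group_abundances": G,
    }
    return Xm, Fm, truth
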