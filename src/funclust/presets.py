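"""Study presets: the configurations used by the packaged synthetic studies.

These are the settings under which the benchmark-recovery, gating, baseline
and consumer-resource studies shipped with the package (examples, test
suite, reproduction script) are run. Network and iteration sizes are scaled
to the 12-species benchmark: a (32, 32) map from three group abundances to a
scalar function is already over-parameterized for that problem, and ~9000
full-batch iterations with the slow annealing rate below lets the assignment
probabilities harden before early stopping can trigger. Library defaults
(RunConfig) remain the larger general-purpose values.
"""

from __future__ import annotations

from .benchmark import BenchmarkSpec, RegimeCoefficients
from .crm import CRMFitConfig
from .io import RunConfig

__all__ = [
    "benchmark_run_config",
    "gated_run_config",
    "GATE_STRENGTH_GRID",
    "linear_coefficients",
    "benchmark_spec",
    "crm_fit_config",
    "crm_null_fit_config",
]

#: L1 gate penalty grid searched in the gating study
GATE_STRENGTH_GRID = (1e-4, 1e-3, 1e-2)


def benchmark_spec(seed: int, n_irrelevant: int = 0) -> BenchmarkSpec:
    """The 12-species / 3-group benchmark at its default size (500 samples)."""
    return BenchmarkSpec(seed=seed, n_irrelevant=n_irrelevant)


def benchmark_run_config(seed: int, **overrides) -> RunConfig:
    """Ensemble training settings for the 12-species benchmark."""
    base = dict(
        n_clusters=3,
        n_ensemble=12,
        learning_rate=1e-2,
        tau_rate=5e-4,
        max_iters=9000,
        early_stop_patience=900,
        hidden_layers=(32, 32),
        top_fraction=0.25,
        seed=seed,
    )
    base.update(overrides)
    return RunConfig(**base)


def gated_run_config(seed: int, gate_strength: float) -> RunConfig:
    """Benchmark settings with the sparsity gate enabled."""
    return benchmark_run_config(seed, gate_strength=gate_strength)


def linear_coefficients() -> RegimeCoefficients:
    """Globally linear benchmark variant: all three regime vectors equal
    (the regime switch then has no effect and f is linear in G)."""
    v = (1.0, -0.5, -0.1)
    return RegimeCoefficients(a1=v, a2=v, a3=v)


def crm_fit_config(seed: int = 0) -> CRMFitConfig:
    """Full-resolution yield grid for parameter-recovery studies."""
    return CRMFitConfig(gamma_grid_size=20, seed=seed)


def crm_null_fit_config(seed: int = 0) -> CRMFitConfig:
    """Coarser yield grid used inside the null-model comparison, where the
    fit is repeated hundreds of times on randomized groupings."""
    return CRMFitConfig(gamma_grid_size=6, seed=seed)
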