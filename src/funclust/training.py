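"""Ensemble training: splits, temperature annealing, gradient descent with
early stopping, hyperparameter grid search, and the cluster-number scan.

One model is trained per random train/test split; the resulting ensemble is
later distilled into a consensus grouping. Training is full batch (the
datasets this method targets are small), with the Gumbel-softmax temperature
annealed exponentially from ``tau_max`` to ``tau_min`` per iteration. Early
stopping monitors the pure mean-squared error on the held-out split,
evaluated with the deterministic argmax clustering (the same clustering the
consensus step uses).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import core
from .io import RunConfig

__all__ = [
    "TrainedMember",
    "Ensemble",
    "split_data",
    "anneal_tau",
    "train_member",
    "train_ensemble",
    "grid_search",
    "scan_ncluster",
]


@dataclass
class TrainedMember:
    model: core.ClusterModel
    split_seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_r2: float
    test_loss: float
    iterations_run: int


@dataclass
class Ensemble:
    members: list
    config: RunConfig


def split_data(n_samples: int, train_fraction: float, seed: int):
    """Disjoint, exhaustive train/test index split; round(frac*N) train samples."""
    if n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_train = int(round(train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def anneal_tau(step: int, config: RunConfig) -> float:
    """tau(step) = max(tau_min, tau_max * exp(-tau_rate * step))."""
    return max(config.tau_min, config.tau_max * float(np.exp(-config.tau_rate * step)))


def _standardizer(F_train: np.ndarray, config: RunConfig):
    """Optional per-column z-scoring of the function block (fit on train).

    Default 'auto': on for multi-column function targets (puts columns on a
    common MSE scale), off for a single scalar function.
    """
    mode = config.standardize_function
    on = (mode == "on") or (mode == "auto" and F_train.shape[1] > 1)
    if not on:
        return lambda F: F
    mu = F_train.mean(axis=0)
    sd = F_train.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda F: (F - mu) / sd


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _SGD:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


def _flat_grads(model: core.ClusterModel, grads: dict):
    gs = [grads["logits"]] + grads["weights"] + grads["biases"]
    if model.gated:
        gs.append(grads["gate_logits"])
    return gs


def _eval_mse(X, F, model):
    """Pure MSE with the deterministic argmax clustering (no gate penalty)."""
    C = core.hard_clustering_matrix(core.hard_assignment(model), model.n_clusters)
    return core.loss(X, F, model, C, beta=0.0)


def train_member(
    X_train: np.ndarray,
    F_train: np.ndarray,
    X_test: np.ndarray,
    F_test: np.ndarray,
    config: RunConfig,
    seed: int,
    split_seed: int = -1,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
) -> TrainedMember:
    """Train one ensemble member by full-batch gradient descent.

    Stops when the held-out MSE has not improved for
    ``early_stop_patience`` iterations or at ``max_iters``; the returned
    model carries the parameters of the best held-out iteration.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    F_train = np.atleast_2d(np.asarray(F_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    F_test = np.atleast_2d(np.asarray(F_test, dtype=float))
    rng = np.random.default_rng(seed)
    model = core.init_model(
        n_features=X_train.shape[1],
        n_clusters=config.n_clusters,
        n_outputs=F_train.shape[1],
        hidden=config.hidden_layers,
        gated=config.gated,
        activation=config.activation,
        seed=rng,
    )
    scale = _standardizer(F_train, config)
    F_tr, F_te = scale(F_train), scale(F_test)

    params = model.flat_params()
    opt_cls = _Adam if config.optimizer == "adam" else _SGD
    opt = opt_cls(params, config.learning_rate)

    best_loss = np.inf
    best_model = model.copy()
    best_iter = 0
    it = 0
    for it in range(1, config.max_iters + 1):
        tau = anneal_tau(it - 1, config)
        value, grads = core.loss_and_grads(
            X_train, F_tr, model, tau=tau, beta=config.gate_strength, rng=rng
        )
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        opt.step(params, _flat_grads(model, grads))

        if it % config.eval_every == 0 or it == config.max_iters:
            test_mse = _eval_mse(X_test, F_te, model)
            if test_mse < best_loss - 1e-12:
                best_loss = test_mse
                best_model = model.copy()
                best_iter = it
            elif it - best_iter >= config.early_stop_patience:
                break

    ss_res = best_loss * X_test.shape[0]
    ss_tot = float(np.sum((F_te - F_te.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return TrainedMember(
        model=best_model,
        split_seed=split_seed,
        train_idx=train_idx if train_idx is not None else np.arange(X_train.shape[0]),
        test_idx=test_idx if test_idx is not None else np.array([], dtype=int),
        test_r2=r2,
        test_loss=best_loss,
        iterations_run=it,
    )


def member_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, pairwise-distinct per-member seeds (< 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(2 * n)
    return (state & 0x7FFFFFFF).astype(np.int64)


def train_ensemble(X: np.ndarray, F: np.ndarray, config: RunConfig) -> Ensemble:
    """Train ``config.n_ensemble`` members on independent random splits.

    Each member's split and initialisation seeds derive deterministically
    from ``config.seed``, so members are independent of training order and
    the whole ensemble is reproducible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    seeds = member_seeds(config.seed, config.n_ensemble)
    members = []
    for mu in range(config.n_ensemble):
        split_seed = int(seeds[2 * mu])
        init_seed = int(seeds[2 * mu + 1])
        tr, te = split_data(X.shape[0], config.train_fraction, split_seed)
        members.append(
            train_member(
                X[tr], F[tr], X[te], F[te], config, seed=init_seed,
                split_seed=split_seed, train_idx=tr, test_idx=te,
            )
        )
    return Ensemble(members=members, config=config)


def grid_search(
    X: np.ndarray,
    F: np.ndarray,
    base_config: RunConfig,
    learning_rates=(1e-3, 3e-3, 1e-2),
    tau_rates=(1e-4, 1e-3, 1e-2),
    gate_strengths=None,
):
    """Train a full ensemble per grid point; select the lowest median held-out MSE.

    ``gate_strengths`` defaults to the base config's beta alone (no gating
    grid) — pass e.g. (1e-4, 1e-3, 1e-2) to include the sparsity penalty in
    the search. Returns (best_config, results) where results is a list of
    dicts (one per grid point) with the trained ensemble attached.
    """
    if gate_strengths is None:
        gate_strengths = (base_config.gate_strength,)
    if not (len(learning_rates) and len(tau_rates) and len(gate_strengths)):
        raise ValueError("grids must be non-empty")
    results = []
    for lr, rt, beta in itertools.product(learning_rates, tau_rates, gate_strengths):
        cfg = base_config.replace(learning_rate=lr, tau_rate=rt, gate_strength=beta)
        ens = train_ensemble(X, F, cfg)
        losses = [m.test_loss for m in ens.members]
        results.append(
            {
                "learning_rate": lr,
                "tau_rate": rt,
                "gate_strength": beta,
                "median_test_loss": float(np.median(losses)),
                "median_test_r2": float(np.median([m.test_r2 for m in ens.members])),
                "ensemble": ens,
            }
        )
    best = min(results, key=lambda r: r["median_test_loss"])
    return best["ensemble"].config, results


def scan_ncluster(X: np.ndarray, F: np.ndarray, config: RunConfig, cluster_range):
    """Median held-out loss versus the number of clusters.

    Returns a list of dicts with per-member and median test losses for each
    cluster count, plus the empirical variance of the (standardised) function
    values as the reference level a constant predictor would attain.
    """
    cluster_range = list(cluster_range)
    if not cluster_range:
        raise ValueError("cluster_range must be non-empty")
    F = np.atleast_2d(np.asarray(F, dtype=float))
    scale = _standardizer(F, config)
    f_var = float(np.mean((scale(F) - scale(F).mean(axis=0)) ** 2) * F.shape[1])
    rows = []
    for k in cluster_range:
        cfg = config.replace(n_clusters=int(k))
        ens = train_ensemble(X, F, cfg)
        losses = [m.test_loss for m in ens.members]
        rows.append(
            {
                "n_clusters": int(k),
                "member_test_losses": losses,
                "median_test_loss": float(np.median(losses)),
                "function_variance": f_var,
                "ensemble": ens,
            }
        )
    return rows
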