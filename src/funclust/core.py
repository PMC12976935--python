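"""Differentiable model for function-informed clustering.

The model maps a sample's feature abundances ``x`` (species, ASVs, gene
modules) to a predicted community function ``f_hat`` in three stages:

1. an optional *gate* ``gamma = sigmoid(l)`` multiplies abundances
   elementwise, so irrelevant features can be switched off;
2. a *clustering matrix* ``C`` with approximately one-hot rows aggregates
   features into ``n_clusters`` group abundances ``g = x C``;
3. a small fully connected network maps ``g`` to ``f_hat``.

``C`` is sampled with the Gumbel-softmax trick from a learned row-stochastic
probability matrix ``P``: ``C = row_softmax((Gamma + log P) / tau)`` with
``Gamma`` i.i.d. standard Gumbel noise. At small temperature ``tau`` the rows
are nearly one-hot, yet the sample remains differentiable in the logits, so
the clustering is learned jointly with the network by gradient descent on the
mean squared prediction error (plus ``beta * ||gamma||_1`` when gating).

Everything here is plain numpy with hand-derived reverse-mode gradients;
`loss_and_grads` is checked against central finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "init_model",
    "sample_clustering",
    "hard_assignment",
    "apply_gate",
    "group_abundances",
    "predict_function",
    "loss",
    "loss_and_grads",
    "mlp_forward",
    "mlp_loss_and_grads",
    "init_mlp",
]

_ACTIVATIONS = ("tanh", "relu", "softplus")


@dataclass
class ClusterModel:
    """Learnable state: cluster logits, optional gate logits, network weights.

    ``logits`` is n_features x n_clusters; its row-wise softmax is the
    assignment probability matrix P. ``gate_logits`` is length n_features or
    None when gating is disabled. ``weights``/``biases`` parameterize the
    fully connected map from group abundances to function.
    """

    logits: np.ndarray
    gate_logits: np.ndarray | None
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)
    activation: str = "tanh"

    @property
    def n_features(self) -> int:
        return self.logits.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.logits.shape[1]

    @property
    def gated(self) -> bool:
        return self.gate_logits is not None

    def probabilities(self) -> np.ndarray:
        """Row-stochastic assignment matrix P (softmax of the logits)."""
        return np.exp(_log_softmax(self.logits))

    def gate(self) -> np.ndarray:
        """Gate values gamma = sigmoid(gate_logits); all ones if ungated."""
        if self.gate_logits is None:
            return np.ones(self.n_features)
        return _sigmoid(self.gate_logits)

    def copy(self) -> "ClusterModel":
        return ClusterModel(
            logits=self.logits.copy(),
            gate_logits=None if self.gate_logits is None else self.gate_logits.copy(),
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activation=self.activation,
        )

    def flat_params(self) -> list:
        ps = [self.logits] + self.weights + self.biases
        if self.gate_logits is not None:
            ps.append(self.gate_logits)
        return ps


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_softmax(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=-1, keepdims=True)
    return zs - np.log(np.exp(zs).sum(axis=-1, keepdims=True))


def _softmax(z: np.ndarray) -> np.ndarray:
    return np.exp(_log_softmax(z))


def init_mlp(n_in: int, n_out: int, hidden: tuple, rng: np.random.Generator):
    """Glorot-scaled random weights for a fully connected network."""
    sizes = [n_in, *hidden, n_out]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (a + b))
        weights.append(rng.normal(0.0, scale, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def init_model(
    n_features: int,
    n_clusters: int,
    n_outputs: int,
    hidden: tuple = (128, 128, 128),
    gated: bool = False,
    activation: str = "tanh",
    gate_init: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> ClusterModel:
    """Fresh model: uniform cluster probabilities (zero logits), open gates.

    Gate logits start at ``gate_init`` (sigmoid(2) ~ 0.88) so that every
    feature initially passes through and the L1 penalty must actively close a
    gate.
    """
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights, biases = init_mlp(n_clusters, n_outputs, tuple(hidden), rng)
    return ClusterModel(
        logits=np.zeros((n_features, n_clusters)),
        gate_logits=np.full(n_features, float(gate_init)) if gated else None,
        weights=weights,
        biases=biases,
        activation=activation,
    )


def sample_gumbel(shape, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. standard Gumbel noise, -log(-log(U))."""
    u = rng.uniform(size=shape)
    return -np.log(-np.log(u))


def sample_clustering(
    model: ClusterModel,
    tau: float,
    rng: np.random.Generator | None = None,
    gumbel: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an approximately one-hot clustering matrix C.

    C = row_softmax((Gamma + log P) / tau). Rows sum to one exactly; as
    tau -> 0 each row approaches the one-hot indicator of a category drawn
    from the corresponding row of P (the Gumbel-max property).
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if gumbel is None:
        if rng is None:
            raise ValueError("provide either rng or a pre-drawn gumbel matrix")
        gumbel = sample_gumbel(model.logits.shape, rng)
    log_p = _log_softmax(model.logits)
    return _softmax((gumbel + log_p) / tau)


def hard_assignment(model: ClusterModel) -> np.ndarray:
    """Deterministic cluster labels: argmax of each row of P (0-based)."""
    return np.argmax(model.logits, axis=1)


def hard_clustering_matrix(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    C = np.zeros((labels.size, n_clusters))
    C[np.arange(labels.size), labels] = 1.0
    return C


def apply_gate(x: np.ndarray, gate_logits: np.ndarray) -> np.ndarray:
    """Gated abundances sigmoid(l) * x (elementwise, broadcasting over rows)."""
    x = np.asarray(x, dtype=float)
    gate_logits = np.asarray(gate_logits, dtype=float)
    if x.shape[-1] != gate_logits.shape[0]:
        raise ValueError(
            f"length mismatch: {x.shape[-1]} abundances vs {gate_logits.shape[0]} gates"
        )
    return x * _sigmoid(gate_logits)


def group_abundances(x: np.ndarray, clustering: np.ndarray) -> np.ndarray:
    """Group abundances g = x C for a row (or batch of rows) x."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != clustering.shape[0]:
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} features vs clustering rows {clustering.shape[0]}"
        )
    return x @ clustering


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "softplus":
        return np.logaddexp(0.0, z)
    raise ValueError(kind)


def _act_grad(z: np.ndarray, h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - h * h
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "softplus":
        return _sigmoid(z)
    raise ValueError(kind)


def mlp_forward(g: np.ndarray, weights, biases, activation: str = "tanh"):
    """Forward pass; returns (output, cache) with per-layer pre/post activations."""
    h = np.atleast_2d(np.asarray(g, dtype=float))
    zs, hs = [], [h]
    for i, (w, b) in enumerate(zip(weights, biases)):
        z = h @ w + b
        zs.append(z)
        h = _act(z, activation) if i < len(weights) - 1 else z
        hs.append(h)
    return h, (zs, hs)


def _mlp_backward(d_out, weights, biases, cache, activation):
    zs, hs = cache
    d_ws = [None] * len(weights)
    d_bs = [None] * len(biases)
    d = d_out
    for i in range(len(weights) - 1, -1, -1):
        d_ws[i] = hs[i].T @ d
        d_bs[i] = d.sum(axis=0)
        d = d @ weights[i].T
        if i > 0:
            d = d * _act_grad(zs[i - 1], hs[i], activation)
    return d, d_ws, d_bs  # d is gradient w.r.t. the network input


def predict_function(g: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Network output f_hat for group abundances g (row or batch)."""
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    out, _ = mlp_forward(g, model.weights, model.biases, model.activation)
    return out[0] if single else out


def predict_from_abundances(
    x: np.ndarray, model: ClusterModel, clustering: np.ndarray | None = None
) -> np.ndarray:
    """End-to-end prediction with a deterministic (argmax) clustering by default."""
    if clustering is None:
        clustering = hard_clustering_matrix(hard_assignment(model), model.n_clusters)
    xg = apply_gate(x, model.gate_logits) if model.gated else np.asarray(x, dtype=float)
    return predict_function(group_abundances(xg, clustering), model)


def loss(
    X: np.ndarray,
    F: np.ndarray,
    model: ClusterModel,
    clustering: np.ndarray,
    beta: float = 0.0,
) -> float:
    """Batch loss for a *given* clustering matrix: mean over samples of the
    squared error norm, plus beta * ||gamma||_1 when gating is enabled."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    xg = apply_gate(X, model.gate_logits) if model.gated else X
    f_hat = predict_function(group_abundances(xg, clustering), model)
    mse = float(np.sum((F - f_hat) ** 2) / X.shape[0])
    if model.gated and beta > 0:
        mse += beta * float(np.sum(model.gate()))
    return mse


def loss_and_grads(
    X: np.ndarray,
    F: np.ndarray,
    model: ClusterModel,
    tau: float,
    beta: float = 0.0,
    rng: np.random.Generator | None = None,
    gumbel: np.ndarray | None = None,
):
    """One stochastic loss evaluation and its exact gradients.

    A single clustering matrix C is sampled (one Gumbel draw shared by the
    whole batch, as in full-batch training) and the loss

        L = (1/B) sum_i ||f_i - f_hat_i||^2  [+ beta * ||gamma||_1]

    is differentiated through the network, the aggregation g = x_g C, the
    row softmax of (Gamma + log P)/tau, the log-softmax producing log P, and
    the gate sigmoid. Returns (loss_value, grads_dict).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    B = X.shape[0]
    if B == 0:
        raise ValueError("empty batch")
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if gumbel is None:
        gumbel = sample_gumbel(model.logits.shape, rng)

    log_p = _log_softmax(model.logits)
    P = np.exp(log_p)
    C = _softmax((gumbel + log_p) / tau)

    if model.gated:
        gamma = _sigmoid(model.gate_logits)
        Xg = X * gamma
    else:
        gamma = None
        Xg = X

    G = Xg @ C
    f_hat, cache = mlp_forward(G, model.weights, model.biases, model.activation)
    resid = f_hat - F
    value = float(np.sum(resid**2) / B)

    d_out = 2.0 * resid / B
    dG, d_ws, d_bs = _mlp_backward(d_out, model.weights, model.biases, cache, model.activation)

    dC = Xg.T @ dG
    dXg = dG @ C.T
    # row-softmax backward, then the 1/tau scaling, then log-softmax backward
    dS = C * (dC - np.sum(dC * C, axis=1, keepdims=True))
    d_log_p = dS / tau
    d_logits = d_log_p - P * np.sum(d_log_p, axis=1, keepdims=True)

    grads = {"logits": d_logits, "weights": d_ws, "biases": d_bs}
    if model.gated:
        value += beta * float(np.sum(gamma))
        d_gamma = np.sum(dXg * X, axis=0) + beta
        grads["gate_logits"] = d_gamma * gamma * (1.0 - gamma)
    return value, grads


def mlp_loss_and_grads(G: np.ndarray, F: np.ndarray, weights, biases, activation="tanh"):
    """MSE loss and gradients for the network alone (fixed inputs G).

    Used by the co-occurrence + neural-map baseline, where the clustering is
    frozen and only the structure-function map is trained.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    f_hat, cache = mlp_forward(G, weights, biases, activation)
    resid = f_hat - F
    value = float(np.sum(resid**2) / G.shape[0])
    d_out = 2.0 * resid / G.shape[0]
    _, d_ws, d_bs = _mlp_backward(d_out, weights, biases, cache, activation)
    return value, d_ws, d_bs
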