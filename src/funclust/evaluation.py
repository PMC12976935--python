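"""Scoring (Jaccard recovery, held-out R-squared) and baseline comparators.

Baselines bracket what the joint method contributes:

* Model I  — function-blind co-occurrence clustering (average-linkage on
  correlation distance) followed by a linear map from group sums to function;
* Model II — the same frozen clustering with a neural structure-function map;
* Model III — function-informed clustering by simulated annealing over hard
  assignments, but restricted to a linear map;
* PCA + linear regression on the leading principal components.

All comparators accept the same train/test split so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import core
from .io import RunConfig
from .training import _Adam, _standardizer

__all__ = [
    "GroupingComparison",
    "jaccard",
    "grouping_agreement",
    "r_squared",
    "cooccurrence_clusters",
    "model_I",
    "model_II",
    "model_III",
    "pca_linear_baseline",
    "linear_on_groups",
]


@dataclass
class GroupingComparison:
    per_group_jaccard: np.ndarray
    total_jaccard: float


def _as_groups(labels) -> dict:
    """{label: set of feature indices} from a label vector or a dict of sets."""
    if isinstance(labels, dict):
        return {k: set(v) for k, v in labels.items()}
    labels = np.asarray(labels)
    return {int(g): set(np.flatnonzero(labels == g).tolist()) for g in np.unique(labels)}


def jaccard(
    truth,
    predicted,
    sum_denominator: bool = False,
    truth_irrelevant_label: int | None = None,
    predicted_active: np.ndarray | None = None,
) -> GroupingComparison:
    """Group-recovery score between two partitions of the same features.

    For truth group i and predicted group j, J_ij = |i ∩ j| / |i ∪ j|
    (or |i ∩ j| / (|i| + |j|) with ``sum_denominator``). Each truth group
    scores its best match, J_i = max_j J_ij, and the total is the mean of
    the J_i.

    When a gate was used, pass ``predicted_active``: inactive features are
    removed from the predicted groups and collected into a predicted
    "irrelevant" class, scored against the truth class with label
    ``truth_irrelevant_label`` when one exists.
    """
    arrays_in = not isinstance(truth, dict) and not isinstance(predicted, dict)
    t = _as_groups(truth)
    p = _as_groups(predicted)
    universe_t = set().union(*t.values()) if t else set()
    universe_p = set().union(*p.values()) if p else set()
    if predicted_active is not None:
        act = np.asarray(predicted_active, dtype=bool)
        inactive = {i for i in universe_p if not act[i]}
        p = {k: v - inactive for k, v in p.items()}
        p = {k: v for k, v in p.items() if v}
        if inactive:
            p[-1] = inactive  # predicted irrelevant class
        if truth_irrelevant_label is None:
            t = {k: v for k, v in t.items()}
    elif arrays_in and universe_t != universe_p:
        # label vectors must describe the same features; explicit group
        # dicts may cover different subsets (e.g. single groups)
        raise ValueError("groupings cover different feature universes")

    def score(si: set, sj: set) -> float:
        inter = len(si & sj)
        denom = (len(si) + len(sj)) if sum_denominator else len(si | sj)
        return inter / denom if denom else 0.0

    # the truth irrelevant class (if any) is matched only against the
    # predicted irrelevant class; real groups never match it
    per = []
    for ti, si in sorted(t.items()):
        if truth_irrelevant_label is not None and ti == truth_irrelevant_label:
            per.append(score(si, p.get(-1, set())))
        else:
            cands = [v for k, v in p.items() if k != -1]
            per.append(max((score(si, sj) for sj in cands), default=0.0))
    per = np.asarray(per)
    return GroupingComparison(per_group_jaccard=per, total_jaccard=float(per.mean()))


def grouping_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of features on which two groupings agree, after optimally
    matching group labels (permutation-invariant)."""
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    ua, ub = np.unique(a), np.unique(b)
    overlap = np.zeros((ua.size, ub.size))
    for i, ga in enumerate(ua):
        for j, gb in enumerate(ub):
            overlap[i, j] = np.sum((a == ga) & (b == gb))
    rows, cols = linear_sum_assignment(-overlap)
    return float(overlap[rows, cols].sum() / a.size)


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination pooled over all entries of the block."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("shape mismatch")
    if obs.size < 2:
        raise ValueError("need at least 2 entries")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ZeroDivisionError("observed block has zero total variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def _lstsq_map(G_train, F_train):
    """Ordinary least squares with intercept; returns a predict(G) callable."""
    A = np.column_stack([G_train, np.ones(G_train.shape[0])])
    coef, *_ = np.linalg.lstsq(A, F_train, rcond=None)
    return lambda G: np.column_stack([G, np.ones(G.shape[0])]) @ coef


def cooccurrence_clusters(X: np.ndarray, n_clusters: int) -> np.ndarray:
    """Function-blind clustering of features from abundance correlations.

    Average-linkage hierarchical clustering on the distance 1 - Pearson r,
    cut at ``n_clusters``; constant features get correlation 0 with
    everything. Returns 1-based labels.
    """
    X = np.asarray(X, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def model_I(X, F, n_clusters, train_idx, test_idx):
    """Co-occurrence clustering + linear map. Returns (labels, test R^2)."""
    X = np.asarray(X, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    labels = cooccurrence_clusters(X, n_clusters)
    C = core.hard_clustering_matrix(labels - 1, int(labels.max()))
    G = X @ C
    predict = _lstsq_map(G[train_idx], F[train_idx])
    return labels, r_squared(F[test_idx], predict(G[test_idx]))


def _train_mlp(G_tr, F_tr, G_te, F_te, config: RunConfig, seed: int):
    """Gradient-trained network from group abundances to function, with the
    same early-stopping rule as the main trainer."""
    rng = np.random.default_rng(seed)
    weights, biases = core.init_mlp(
        G_tr.shape[1], F_tr.shape[1], config.hidden_layers, rng
    )
    params = weights + biases
    opt = _Adam(params, config.learning_rate)
    best = (np.inf, [w.copy() for w in weights], [b.copy() for b in biases], 0)
    for it in range(1, config.max_iters + 1):
        _, d_ws, d_bs = core.mlp_loss_and_grads(G_tr, F_tr, weights, biases, config.activation)
        opt.step(params, d_ws + d_bs)
        pred, _ = core.mlp_forward(G_te, weights, biases, config.activation)
        test_mse = float(np.sum((F_te - pred) ** 2) / G_te.shape[0])
        if test_mse < best[0] - 1e-12:
            best = (test_mse, [w.copy() for w in weights], [b.copy() for b in biases], it)
        elif it - best[3] >= config.early_stop_patience:
            break
    _, weights, biases = best[0], best[1], best[2]
    return lambda G: core.mlp_forward(G, weights, biases, config.activation)[0]


def model_II(X, F, n_clusters, train_idx, test_idx, config: RunConfig, seed: int = 0):
    """Co-occurrence clustering (same as Model I) + neural map."""
    X = np.asarray(X, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    labels = cooccurrence_clusters(X, n_clusters)
    C = core.hard_clustering_matrix(labels - 1, int(labels.max()))
    G = X @ C
    scale = _standardizer(F[train_idx], config)
    predict = _train_mlp(G[train_idx], scale(F[train_idx]), G[test_idx], scale(F[test_idx]), config, seed)
    return labels, r_squared(scale(F[test_idx]), predict(G[test_idx]))


def model_III(
    X,
    F,
    n_clusters,
    train_idx,
    test_idx,
    n_moves: int = 20000,
    n_restarts: int = 5,
    seed: int = 0,
    t_start: float = 1.0,
    t_end: float = 1e-3,
):
    """Function-informed clustering by simulated annealing with a linear map.

    State: a hard assignment of features to groups. Move: reassign one
    random feature to a random other group. Objective: train-split MSE of
    the best linear map from group sums to F. Geometric temperature
    schedule; best state over all restarts wins. Returns (labels, test R^2).
    """
    X = np.asarray(X, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = X.shape[1]
    rng = np.random.default_rng(seed)
    Xtr, Ftr = X[train_idx], F[train_idx]

    def objective(labels):
        C = core.hard_clustering_matrix(labels, n_clusters)
        pred = _lstsq_map(Xtr @ C, Ftr)(Xtr @ C)
        return float(np.mean(np.sum((Ftr - pred) ** 2, axis=1)))

    best_labels, best_obj = None, np.inf
    for _ in range(max(n_restarts, 1)):
        labels = rng.integers(0, n_clusters, size=n)
        obj = objective(labels)
        cur_best_labels, cur_best_obj = labels.copy(), obj
        for move in range(n_moves):
            temp = t_start * (t_end / t_start) ** (move / max(n_moves - 1, 1))
            i = int(rng.integers(n))
            new = int(rng.integers(n_clusters - 1))
            if new >= labels[i]:
                new += 1
            old = labels[i]
            labels[i] = new
            cand = objective(labels)
            if cand <= obj or rng.uniform() < np.exp(-(cand - obj) / temp):
                obj = cand
                if cand < cur_best_obj:
                    cur_best_labels, cur_best_obj = labels.copy(), cand
            else:
                labels[i] = old
        if cur_best_obj < best_obj:
            best_labels, best_obj = cur_best_labels, cur_best_obj

    C = core.hard_clustering_matrix(best_labels, n_clusters)
    G = X @ C
    predict = _lstsq_map(G[train_idx], F[train_idx])
    return best_labels + 1, r_squared(F[test_idx], predict(G[test_idx]))


def pca_linear_baseline(X, F, n_components, train_idx, test_idx) -> float:
    """Linear regression of F on the leading principal components of X."""
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LinearRegression

    X = np.asarray(X, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if n_components > min(len(train_idx), X.shape[1]):
        raise ValueError("n_components exceeds the training data rank bound")
    pca = PCA(n_components=n_components).fit(X[train_idx])
    Z = pca.transform(X)
    reg = LinearRegression().fit(Z[train_idx], F[train_idx])
    return r_squared(F[test_idx], reg.predict(Z[test_idx]))


def linear_on_groups(X, F, labels, train_idx, test_idx) -> float:
    """OLS from the group sums of a given (1-based) grouping to F; test R^2."""
    X = np.asarray(X, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    labels = np.asarray(labels, dtype=int)
    groups = np.unique(labels[labels > 0])
    G = np.column_stack([X[:, labels == g].sum(axis=1) for g in groups])
    predict = _lstsq_map(G[train_idx], F[train_idx])
    return r_squared(F[test_idx], predict(G[test_idx]))
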