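"""Consensus grouping extraction from a trained ensemble.

Independently trained members differ through their random train/test splits
and the stochastic Gumbel sampling, and their group labels are only defined
up to permutation. Consensus proceeds in three steps: (1) keep the
top-performing fraction of members by held-out R-squared; (2) align group
labels across members by sorting groups on a common key (average group
abundance by default, or correlation with a designated function column);
(3) majority-vote each feature's label, and — when gating was used — mark a
feature active only if its gate is open (gamma >= 0.5) in a strict majority
of the selected members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import core
from .training import Ensemble, TrainedMember

__all__ = ["ConsensusGrouping", "rank_and_select", "align_labels", "consensus", "extract_consensus"]


@dataclass
class ConsensusGrouping:
    """Per-feature consensus label (1-based), active flag and vote agreement."""

    feature_ids: list
    labels: np.ndarray  # group index in 1..n_clusters
    active: np.ndarray  # False = gated out
    agreement: np.ndarray  # fraction of selected members voting the winner
    top_fraction_used: float = 1.0

    def groups(self, active_only: bool = True) -> dict:
        """Mapping group label -> set of feature ids (active features only
        by default)."""
        out: dict = {}
        for fid, lab, act in zip(self.feature_ids, self.labels, self.active):
            if active_only and not act:
                continue
            out.setdefault(int(lab), set()).add(fid)
        return out


def rank_and_select(ensemble: Ensemble | list, top_fraction: float = 0.5) -> list:
    """Members sorted by held-out R-squared (descending); keep the top
    ceil(top_fraction * n) of them."""
    members = ensemble.members if isinstance(ensemble, Ensemble) else list(ensemble)
    if not members:
        raise ValueError("empty ensemble")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    ranked = sorted(members, key=lambda m: -m.test_r2)
    keep = math.ceil(top_fraction * len(ranked))
    return ranked[:keep]


def _alignment_key(member: TrainedMember, X: np.ndarray, F_col: np.ndarray | None) -> np.ndarray:
    """Per-group sort key: mean group abundance over the full dataset, or the
    correlation of group abundance with a designated function column."""
    model = member.model
    labels = core.hard_assignment(model)
    C = core.hard_clustering_matrix(labels, model.n_clusters)
    G = np.asarray(X, dtype=float) @ C
    if F_col is None:
        return G.mean(axis=0)
    f = np.asarray(F_col, dtype=float).ravel()
    key = np.zeros(model.n_clusters)
    for k in range(model.n_clusters):
        if G[:, k].std() > 0 and f.std() > 0:
            key[k] = np.corrcoef(G[:, k], f)[0, 1]
    return key


def _permute_member(member: TrainedMember, perm: np.ndarray) -> TrainedMember:
    """Relabel a member's groups: new group j is old group perm[j]. The first
    network layer's input rows are permuted consistently so predictions are
    unchanged."""
    model = member.model.copy()
    model.logits = model.logits[:, perm]
    model.weights[0] = model.weights[0][perm, :]
    out = TrainedMember(**{**member.__dict__})
    out.model = model
    return out


def align_labels(
    members: list,
    X: np.ndarray,
    function_column: np.ndarray | None = None,
) -> list:
    """Resolve label permutation-invariance across members.

    Groups are reordered within each member by descending alignment key
    (average group abundance, or correlation with ``function_column``). If a
    member's keys tie exactly, it falls back to maximal-overlap matching of
    its hard assignment against the top-ranked member's.
    """
    if not members:
        return []
    ks = {m.model.n_clusters for m in members}
    if len(ks) != 1:
        raise ValueError("members must share n_clusters")
    n_clusters = ks.pop()
    aligned = []
    ref_labels = None
    for m in members:
        key = _alignment_key(m, X, function_column)
        if np.unique(np.round(key, 12)).size == n_clusters:
            perm = np.argsort(-key)
        else:
            # degenerate key: match to the reference member by overlap
            if ref_labels is None:
                perm = np.argsort(-key, kind="stable")
            else:
                labels = core.hard_assignment(m.model)
                overlap = np.zeros((n_clusters, n_clusters))
                for j in range(n_clusters):
                    for k in range(n_clusters):
                        overlap[j, k] = np.sum((ref_labels == j) & (labels == k))
                rows, cols = linear_sum_assignment(-overlap)
                perm = cols[np.argsort(rows)]
        am = _permute_member(m, np.asarray(perm))
        if ref_labels is None:
            ref_labels = core.hard_assignment(am.model)
        aligned.append(am)
    return aligned


def consensus(
    members: list,
    feature_ids: list | None = None,
    gating_enabled: bool | None = None,
    top_fraction_used: float = 1.0,
) -> ConsensusGrouping:
    """Majority-vote consensus over aligned members.

    Each feature's label is the modal argmax assignment across members; vote
    ties break toward the group with larger mean assignment probability, then
    toward the lower group index. A feature is active iff gamma >= 0.5 in a
    strict majority of members (all-active when gating is disabled).
    """
    if not members:
        raise ValueError("no members")
    if gating_enabled is None:
        gating_enabled = members[0].model.gated
    n_features = members[0].model.n_features
    n_clusters = members[0].model.n_clusters
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_features)]

    votes = np.zeros((n_features, n_clusters), dtype=int)
    mean_p = np.zeros((n_features, n_clusters))
    open_counts = np.zeros(n_features, dtype=int)
    for m in members:
        labels = core.hard_assignment(m.model)
        votes[np.arange(n_features), labels] += 1
        mean_p += m.model.probabilities()
        if m.model.gated:
            open_counts += (m.model.gate() >= 0.5).astype(int)
    mean_p /= len(members)

    labels = np.empty(n_features, dtype=int)
    agreement = np.empty(n_features)
    for i in range(n_features):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if tied.size > 1:
            best_p = mean_p[i, tied].max()
            tied = tied[np.isclose(mean_p[i, tied], best_p)]
        labels[i] = tied[0] + 1
        agreement[i] = top / len(members)

    if gating_enabled:
        active = open_counts > len(members) / 2
    else:
        active = np.ones(n_features, dtype=bool)
    return ConsensusGrouping(
        feature_ids=list(feature_ids),
        labels=labels,
        active=active,
        agreement=agreement,
        top_fraction_used=top_fraction_used,
    )


def extract_consensus(
    ensemble: Ensemble,
    X: np.ndarray,
    feature_ids: list | None = None,
    top_fraction: float | None = None,
    function_column: np.ndarray | None = None,
) -> ConsensusGrouping:
    """rank_and_select -> align_labels -> consensus, in one call."""
    tf = top_fraction if top_fraction is not None else ensemble.config.top_fraction
    selected = rank_and_select(ensemble, tf)
    aligned = align_labels(selected, X, function_column)
    return consensus(aligned, feature_ids=feature_ids, top_fraction_used=tf)
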