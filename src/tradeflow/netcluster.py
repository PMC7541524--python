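"""Community structure of yearly directed weighted trade networks.

Partitions are scored with the directed weighted modularity

    Q = (1/w) sum_{ij in same cluster} [ w_ij - w_i^out w_j^in / w ]

(self-pairs included; the trade tensor has no self-loops so their flow term
is zero).  An exact optimiser (branch-and-bound over set partitions) is
available for small graphs, a deterministic greedy agglomeration scales to
the full network, and a walktrap-style random-walk agglomeration provides
the cross-algorithm robustness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, ward
from sklearn.metrics import adjusted_rand_score

from tradeflow.errors import ValidationError
from tradeflow.trade_io import TradeTensor

EXACT_LIMIT_DEFAULT = 16


@dataclass
class Partition:
    """A clustering of countries for one year with its modularity score."""

    assignment: dict
    modularity: float
    method: str
    year: int | None = None

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.assignment[v] for v in nodes])

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict:
        out: dict = {}
        for node, lab in self.assignment.items():
            out.setdefault(lab, []).append(node)
        return out

    def major_clusters(self, min_size: int = 11) -> list:
        """Cluster labels with more than 10 members (the reporting rule)."""
        return [lab for lab, members in self.clusters().items() if len(members) >= min_size]


# ---------------------------------------------------------------------------
# graph plumbing


def _as_matrix(graph):
    """Coerce a digraph / weight matrix into (node labels, dense W)."""
    if isinstance(graph, (nx.DiGraph, nx.Graph)):
        nodes = list(graph.nodes())
        w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
        return nodes, w
    w = np.asarray(graph, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    return list(range(w.shape[0])), w


def graph_from_tensor(tensor: TradeTensor, year: int) -> nx.DiGraph:
    """Directed weighted graph of one year's flows (zero edges omitted)."""
    w = tensor.year_matrix(year)
    g = nx.DiGraph()
    g.add_nodes_from(tensor.countries)
    for i, u in enumerate(tensor.countries):
        for j, v in enumerate(tensor.countries):
            if i != j and w[i, j] > 0:
                g.add_edge(u, v, weight=float(w[i, j]))
    return g


def _modularity_terms(w: np.ndarray):
    total = w.sum()
    if total <= 0:
        raise ValidationError("graph has zero total weight")
    kout = w.sum(axis=1)
    kin = w.sum(axis=0)
    # pair_gain[i, j]: change in Q from i and j sharing a cluster (i != j)
    pair_gain = (w + w.T) / total - (np.outer(kout, kin) + np.outer(kin, kout)) / total**2
    diag = float(np.sum(np.diag(w)) / total - np.sum(kout * kin) / total**2)
    return total, pair_gain, diag


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (lexicographic form)."""
    mapping: dict = {}
    out = np.empty_like(labels)
    for idx, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# scoring


def directed_modularity(graph, partition) -> float:
    """Directed weighted modularity of a partition.

    ``partition`` may be a :class:`Partition`, a mapping node -> label, or a
    label array aligned with the graph's node order.  Invariant under
    cluster relabeling and uniform weight scaling; one big cluster scores
    exactly zero.
    """
    nodes, w = _as_matrix(graph)
    if isinstance(partition, Partition):
        labels = partition.labels_for(nodes)
    elif isinstance(partition, dict):
        labels = np.array([partition[v] for v in nodes])
    else:
        labels = np.asarray(partition)
        if labels.shape[0] != len(nodes):
            raise ValidationError("label vector length mismatch")
    total = w.sum()
    if total <= 0:
        raise ValidationError("graph has zero total weight")
    kout = w.sum(axis=1)
    kin = w.sum(axis=0)
    same = labels[:, None] == labels[None, :]
    q = np.sum(np.where(same, w / total - np.outer(kout, kin) / total**2, 0.0))
    return float(q)


# ---------------------------------------------------------------------------
# optimisers


def exact_modularity_partition(graph, exact_limit: int = EXACT_LIMIT_DEFAULT) -> Partition:
    """Globally modularity-maximal partition by branch-and-bound.

    Enumerates set partitions in restricted-growth order, pruning branches
    whose optimistic bound (current score plus every still-available
    positive pair gain) cannot beat the incumbent.  Ties are broken toward
    fewer clusters, then lexicographically smallest assignment.
    """
    nodes, w = _as_matrix(graph)
    n = len(nodes)
    if n > exact_limit:
        raise ValidationError(
            f"{n} nodes exceeds the exact-search limit ({exact_limit}); "
            "use greedy_modularity_partition"
        )
    total, pair_gain, diag = _modularity_terms(w)

    # optimistic gain from all pairs whose second node is still unassigned
    pos_suffix = np.zeros(n + 1)
    for j in range(n - 1, -1, -1):
        pos_suffix[j] = pos_suffix[j + 1] + float(
            np.sum(np.maximum(pair_gain[:j, j], 0.0))
        )

    labels = np.zeros(n, dtype=int)
    best = {"q": -np.inf, "labels": None, "k": n + 1}

    def consider(q: float) -> None:
        k = len(set(labels[:n]))
        if q > best["q"] + 1e-12 or (
            abs(q - best["q"]) <= 1e-12 and k < best["k"]
        ):
            best["q"] = q
            best["labels"] = labels.copy()
            best["k"] = k

    def recurse(v: int, q: float, max_label: int) -> None:
        if v == n:
            consider(q)
            return
        if q + pos_suffix[v] < best["q"] - 1e-12:
            return
        for lab in range(max_label + 2):
            members = np.flatnonzero(labels[:v] == lab)
            gain = float(pair_gain[members, v].sum()) if members.size else 0.0
            labels[v] = lab
            recurse(v + 1, q + gain, max(max_label, lab))
        labels[v] = 0

    labels[0] = 0
    recurse(1, diag, 0)
    assignment = dict(zip(nodes, _canonical(best["labels"])))
    return Partition(assignment=assignment, modularity=float(best["q"]), method="exact")


def greedy_modularity_partition(graph, seed: int | None = None) -> Partition:
    """Deterministic agglomerative modularity maximisation.

    Starts from singletons and repeatedly merges the cluster pair with the
    largest positive modularity gain (ties go to the smallest label pair),
    then refines with single-node moves until no move improves the score.
    ``seed`` is accepted for interface symmetry — the procedure is fully
    deterministic.
    """
    nodes, w = _as_matrix(graph)
    n = len(nodes)
    total, pair_gain, diag = _modularity_terms(w)

    labels = np.arange(n)
    q = diag

    def merge_pass() -> bool:
        """Merge cluster pairs with the best positive gain until none left."""
        nonlocal q
        changed = False
        while True:
            reps = sorted(set(labels.tolist()))
            best_gain, best_pair = 1e-12, None
            for ai, a in enumerate(reps):
                in_a = labels == a
                for b in reps[ai + 1 :]:
                    gain = float(pair_gain[np.ix_(in_a, labels == b)].sum())
                    if gain > best_gain:
                        best_gain, best_pair = gain, (a, b)
            if best_pair is None:
                return changed
            a, b = best_pair
            labels[labels == b] = a
            q += best_gain
            changed = True

    def move_pass() -> bool:
        """Relocate single nodes (incl. to a fresh cluster) while Q improves."""
        nonlocal q
        changed = False
        improved = True
        while improved:
            improved = False
            for v in range(n):
                own = labels[v]
                others = (labels == own) & (np.arange(n) != v)
                stay = float(pair_gain[v, others].sum())
                best_gain, best_lab = 1e-12, own
                for lab in sorted(set(labels.tolist()) - {own}):
                    gain = float(pair_gain[v, labels == lab].sum()) - stay
                    if gain > best_gain:
                        best_gain, best_lab = gain, lab
                if -stay > best_gain:  # split v off into its own cluster
                    best_gain, best_lab = -stay, int(labels.max()) + 1
                if best_lab != own:
                    labels[v] = best_lab
                    q += best_gain
                    improved = changed = True
        return changed

    # alternate agglomeration and node moves until a joint fixed point
    while True:
        changed = merge_pass()
        changed |= move_pass()
        if not changed:
            break

    assignment = dict(zip(nodes, _canonical(labels)))
    return Partition(assignment=assignment, modularity=float(q), method="greedy")


def walktrap_partition(graph, steps: int = 4) -> Partition:
    """Random-walk community detection on the symmetrised graph.

    Node profiles are rows of P^steps (P the random-walk transition matrix
    on w_ij + w_ji), scaled by inverse square-root strength so Euclidean
    distance is the walk distance; clusters are agglomerated by Ward
    linkage and the dendrogram is cut where the directed modularity of the
    original graph is maximal.  Components are separated automatically by
    the walk distances.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    nodes, w = _as_matrix(graph)
    n = len(nodes)
    total = w.sum()
    if total <= 0:
        raise ValidationError("graph has zero total weight")
    wsym = w + w.T
    strength = wsym.sum(axis=1)
    p = np.eye(n)
    safe = strength > 0
    p[safe] = wsym[safe] / strength[safe, None]
    pt = np.linalg.matrix_power(p, steps)
    scale = np.where(strength > 0, 1.0 / np.sqrt(strength), 1.0)
    features = pt * scale[None, :]

    if n == 1:
        return Partition({nodes[0]: 0}, float("nan"), "walktrap")
    linkage = ward(features)
    best_q, best_labels = -np.inf, np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        labels = fcluster(linkage, t=k, criterion="maxclust")
        q = directed_modularity(w, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    assignment = dict(zip(nodes, _canonical(best_labels)))
    return Partition(assignment=assignment, modularity=float(best_q), method="walktrap")


def k_core_levels(graph) -> dict:
    """Core number per node on the binarised graph (total in+out degree)."""
    nodes, w = _as_matrix(graph)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    idx = np.argwhere(w > 0)
    for i, j in idx:
        if i != j:
            g.add_edge(nodes[i], nodes[j])
    return dict(nx.core_number(g))


def compare_partitions(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same country set."""
    if set(p1.assignment) != set(p2.assignment):
        raise ValidationError("partitions cover different country sets")
    keys = sorted(p1.assignment)
    a = [p1.assignment[k] for k in keys]
    b = [p2.assignment[k] for k in keys]
    return float(adjusted_rand_score(a, b))
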