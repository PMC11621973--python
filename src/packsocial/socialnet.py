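"""Association networks: co-occurrence, centrality, modularity, clustering.

Association follows the gambit of the group at the recording level: every
pair of individuals identified in the same 30-s recording scores one
association. Edge weights are either raw co-occurrence counts or the
simple-ratio index SRI = x / (n_i + n_j - x), the fraction of the dyad's
sightings in which the two were together.

Network structure is summarised by eigenvector centrality (leading
eigenvector of the weight matrix, scaled to a maximum of 1) and by the
weighted Newman modularity

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) [c_i = c_j],

optimised greedily by Clauset-Newman-Moore agglomeration: start from
singleton communities and repeatedly merge the connected pair with the
largest modularity gain, returning the partition at the maximum of the
modularity trace. Q > 0.3 is conventionally read as strong community
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .obs_model import UNIDENTIFIED, ObservationLog

__all__ = [
    "SightingSummary",
    "SocialNetwork",
    "CentralityScores",
    "Partition",
    "MergeDendrogram",
    "DisconnectedNetworkError",
    "cooccurrence_counts",
    "association_matrix",
    "eigenvector_centrality",
    "modularity_q",
    "fast_greedy_partition",
    "connected_components",
]

STRONG_STRUCTURE_THRESHOLD = 0.3


class DisconnectedNetworkError(ValueError):
    """The association graph on nonzero weights is not connected."""


@dataclass
class SightingSummary:
    """Recording-level sighting tallies: ``x[i, j]`` = recordings with both
    i and j; the diagonal holds per-individual totals n_i."""

    ids: tuple[str, ...]
    x: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        x = np.asarray(self.x, dtype=np.int64)
        k = len(self.ids)
        if x.shape != (k, k):
            raise ValueError(f"x shape {x.shape} != ({k}, {k})")
        if not np.array_equal(x, x.T):
            raise ValueError("sighting matrix must be symmetric")
        if (x < 0).any():
            raise ValueError("negative sighting count")
        n = np.diagonal(x)
        if (x > np.minimum.outer(n, n)).any():
            raise ValueError("x_ij exceeds min(n_i, n_j)")
        self.x = x

    @property
    def n(self) -> np.ndarray:
        """Per-individual recording counts."""
        return np.diagonal(self.x).copy()


@dataclass
class SocialNetwork:
    """Weighted undirected association graph over named nodes."""

    ids: tuple[str, ...]
    weights: np.ndarray
    weight_kind: str = "count"

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        w = np.asarray(self.weights, dtype=float)
        k = len(self.ids)
        if w.shape != (k, k):
            raise ValueError(f"weights shape {w.shape} != ({k}, {k})")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("negative weight")
        if np.diagonal(w).any():
            raise ValueError("self-loops are not allowed")
        if self.weight_kind == "sri" and (w > 1 + 1e-12).any():
            raise ValueError("simple-ratio weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (source, target, weight), source < target."""
        out = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.weights[i, j] > 0:
                    out.append((self.ids[i], self.ids[j], float(self.weights[i, j])))
        return out


@dataclass(frozen=True)
class CentralityScores:
    """Eigenvector centrality per node, scaled so the maximum is 1."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.scores))


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment, with the modularity it achieves."""

    labels: Mapping[str, Hashable]
    q: float
    strong_structure: bool

    def communities(self) -> list[frozenset[str]]:
        groups: dict[Hashable, set[str]] = {}
        for node, lab in self.labels.items():
            groups.setdefault(lab, set()).add(node)
        return sorted(
            (frozenset(g) for g in groups.values()), key=lambda g: sorted(g)
        )

    def n_communities(self) -> int:
        return len(set(self.labels.values()))


@dataclass(frozen=True)
class MergeDendrogram:
    """CNM merge history: (label_a, label_b) pairs and the modularity trace.

    ``q_trace[0]`` is the singleton-partition modularity; ``q_trace[k]`` the
    modularity after the k-th merge. ``best`` indexes the trace maximum.
    """

    merges: tuple[tuple[str, str], ...]
    q_trace: tuple[float, ...]
    best: int


def cooccurrence_counts(
    log: ObservationLog,
    node_ids: Sequence[str],
    collapse_map: Mapping[str, str] | None = None,
) -> SightingSummary:
    """Tally per-recording sightings and co-sightings.

    ``collapse_map`` maps raw roster ids onto (possibly merged) node ids —
    e.g. every pup id onto a single "Pups" node; a recording containing two
    pups then counts once for the merged node. Recordings containing
    unidentified animals still count for their identified occupants.
    """
    if not log.events:
        raise ValueError("cannot tally co-occurrence from an empty log")
    node_ids = tuple(node_ids)
    if not node_ids:
        raise ValueError("node_ids must be non-empty")
    collapse = dict(collapse_map or {})
    idx = {code: i for i, code in enumerate(node_ids)}
    x = np.zeros((len(node_ids), len(node_ids)), dtype=np.int64)
    for events in log.recordings().values():
        occupants: set[str] = set()
        for ev in events:
            occupants |= ev.identified_participants()
            if ev.actor != UNIDENTIFIED:
                occupants.add(ev.actor)
        nodes = sorted({collapse.get(code, code) for code in occupants} & set(idx))
        for a in nodes:
            x[idx[a], idx[a]] += 1
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                x[idx[a], idx[b]] += 1
                x[idx[b], idx[a]] += 1
    return SightingSummary(ids=node_ids, x=x)


def association_matrix(
    summary: SightingSummary, weight_kind: str = "count"
) -> SocialNetwork:
    """Edge weights from sighting tallies: raw counts or the simple-ratio index."""
    x = summary.x.astype(float)
    n = summary.n.astype(float)
    if weight_kind == "count":
        w = x.copy()
    elif weight_kind == "sri":
        denom = np.add.outer(n, n) - x
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        raise ValueError(f"unknown weight_kind {weight_kind!r}")
    np.fill_diagonal(w, 0.0)
    return SocialNetwork(ids=summary.ids, weights=w, weight_kind=weight_kind)


def connected_components(network: SocialNetwork) -> list[list[int]]:
    """Connected components (as index lists) of the nonzero-weight graph."""
    n = network.n_nodes
    seen = [False] * n
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(network.weights[u] > 0)[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(sorted(comp))
    return comps


def _require_connected(network: SocialNetwork, largest_component: bool) -> SocialNetwork:
    comps = connected_components(network)
    if len(comps) == 1:
        return network
    if not largest_component:
        raise DisconnectedNetworkError(
            f"network has {len(comps)} components; pass largest_component=True "
            f"to restrict to the largest"
        )
    comp = max(comps, key=lambda c: (len(c), [-i for i in c]))
    sub = network.weights[np.ix_(comp, comp)]
    return SocialNetwork(
        ids=tuple(network.ids[i] for i in comp),
        weights=sub,
        weight_kind=network.weight_kind,
    )


def eigenvector_centrality(
    network: SocialNetwork,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    largest_component: bool = False,
) -> CentralityScores:
    """Leading-eigenvector centrality, maximum score scaled to exactly 1.

    Power iteration from the uniform vector on the Perron-shifted matrix
    A + cI (c = max row sum): the shift leaves the leading eigenvector of a
    nonnegative symmetric matrix unchanged while making its eigenvalue
    strictly dominant, so the iteration also converges on bipartite-like
    graphs whose extreme eigenvalues are otherwise equal in magnitude.
    Convergence: successive max-normalised iterates differ by < tol in
    max-norm.
    """
    if not (network.weights > 0).any():
        raise ValueError("all-zero weight matrix has no centrality")
    net = _require_connected(network, largest_component)
    a = net.weights
    shift = float(a.sum(axis=1).max())
    v = np.full(net.n_nodes, 1.0)
    v /= v.max()
    for _ in range(max_iter):
        nxt = a @ v + shift * v
        nxt /= nxt.max()
        if np.max(np.abs(nxt - v)) < tol:
            v = nxt
            break
        v = nxt
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} steps")
    v = v / v.max()
    return CentralityScores(ids=net.ids, scores=tuple(float(s) for s in v))


def modularity_q(
    network: SocialNetwork, partition: Mapping[str, Hashable]
) -> float:
    """Weighted Newman modularity of a node->community assignment."""
    missing = set(network.ids) - set(partition)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)}")
    a = network.weights
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an all-zero network")
    k = a.sum(axis=1)
    labels = [partition[code] for code in network.ids]
    same = np.equal.outer(np.array(labels, dtype=object), np.array(labels, dtype=object))
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


def fast_greedy_partition(
    network: SocialNetwork, largest_component: bool = False
) -> tuple[Partition, MergeDendrogram]:
    """Clauset-Newman-Moore greedy modularity agglomeration.

    Starting from singleton communities, repeatedly merge the pair of
    currently *connected* communities with the largest modularity gain
    (ties broken by the lexicographically smallest pair of community
    labels, a community being labelled by its smallest member id). Returns
    the partition at the maximum of the modularity trace, flagged
    ``strong_structure`` when that maximum exceeds 0.3, together with the
    full dendrogram.
    """
    net = _require_connected(network, largest_component)
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes to cluster")
    a = net.weights
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("cannot cluster an all-zero network")

    # community state: label -> (member index set); e[l1][l2] = fraction of
    # edge weight between communities; deg[l] = fraction of total degree
    members: dict[str, set[int]] = {net.ids[i]: {i} for i in range(n)}
    deg = {net.ids[i]: float(a[i].sum() / two_m) for i in range(n)}
    e: dict[str, dict[str, float]] = {lab: {} for lab in members}
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                e[net.ids[i]][net.ids[j]] = float(a[i, j] / two_m)

    def current_q() -> float:
        # Q = sum_c (e_cc - deg_c^2); singleton e_cc = 0 (no self-loops)
        q = 0.0
        for lab in members:
            q += e[lab].get(lab, 0.0) - deg[lab] ** 2
        return q

    q = current_q()
    q_trace = [q]
    merges: list[tuple[str, str]] = []
    snapshots: list[dict[str, str]] = [
        {net.ids[i]: net.ids[i] for i in range(n)}
    ]

    while len(members) > 1:
        best_pair: tuple[str, str] | None = None
        best_dq = -np.inf
        for l1 in sorted(members):
            for l2 in sorted(e[l1]):
                if l2 <= l1:
                    continue
                dq = 2.0 * (e[l1].get(l2, 0.0) - deg[l1] * deg[l2])
                if dq > best_dq + 1e-15 or (
                    abs(dq - best_dq) <= 1e-15
                    and best_pair is not None
                    and (l1, l2) < best_pair
                ):
                    best_dq = dq
                    best_pair = (l1, l2)
        if best_pair is None:  # no connected pairs left (disconnected guard)
            break
        l1, l2 = best_pair
        new = min(l1, l2)
        old = max(l1, l2)
        members[new] = members[l1] | members[l2]
        del members[old]
        deg[new] = deg[l1] + deg[l2]
        del deg[old]
        merged_e: dict[str, float] = {}
        for src in (l1, l2):
            for tgt, w in e[src].items():
                if tgt in (l1, l2):
                    merged_e[new] = merged_e.get(new, 0.0) + w
                else:
                    merged_e[tgt] = merged_e.get(tgt, 0.0) + w
        e[new] = merged_e
        if old in e:
            del e[old]
        for lab in list(e):
            if lab == new:
                continue
            row = e[lab]
            w = row.pop(l1, 0.0) + row.pop(l2, 0.0)
            if w:
                row[new] = row.get(new, 0.0) + w
        q += best_dq
        q_trace.append(q)
        merges.append((l1, l2))
        snapshot = {}
        for lab, idxs in members.items():
            for i in idxs:
                snapshot[net.ids[i]] = lab
        snapshots.append(snapshot)

    best = int(np.argmax(q_trace))
    best_q = float(q_trace[best])
    partition = Partition(
        labels=dict(snapshots[best]),
        q=best_q,
        strong_structure=best_q > STRONG_STRUCTURE_THRESHOLD,
    )
    dendrogram = MergeDendrogram(
        merges=tuple(merges),
        q_trace=tuple(float(v) for v in q_trace),
        best=best,
    )
    return partition, dendrogram
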