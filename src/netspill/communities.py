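"""Modularity and the two modularity-maximizing community detectors.

Communities — groups of participants densely connected internally with only
sparse connections outward — define the interference sets for the causal
analysis: spillover is assumed possible within a community but not across
communities (partial interference).

Two classic detectors are provided:

* greedy agglomerative merging (start from singletons, repeatedly apply the
  merge with the largest modularity increase, stop when no merge increases
  modularity), and
* leading-eigenvector recursive bisection of the (generalized) modularity
  matrix, accepting a split only when it strictly increases modularity.

Both run per connected component — a component's community structure should
not depend on the rest of the graph — and labels are unified globally
afterwards.  All tie-breaks are deterministic so that repeated runs on the
same graph give identical partitions on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.linalg

__all__ = [
    "CommunityStructure",
    "modularity",
    "detect_greedy_agglomerative",
    "detect_leading_eigenvector",
]

_DQ_TOL = 1e-12     # a merge/split must beat this to count as an increase
_EIG_TOL = 1e-10    # leading eigenvalue below this => indivisible group


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


@dataclass
class CommunityStructure:
    """A partition of the graph's nodes into communities labeled 1..N."""

    assignment: dict[Hashable, int]
    method: str = "given"
    modularity: float | None = None

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(1, len(labels) + 1)):
            # renumber to contiguous 1..N preserving label order
            relabel = {old: new for new, old in enumerate(labels, start=1)}
            self.assignment = {n: relabel[c] for n, c in self.assignment.items()}

    @classmethod
    def from_membership(cls, nodes: Sequence, labels: Sequence[int], **kw) -> "CommunityStructure":
        return cls(assignment=dict(zip(nodes, labels)), **kw)

    @property
    def n_communities(self) -> int:
        return max(self.assignment.values(), default=0)

    @property
    def sizes(self) -> list[int]:
        counts = [0] * self.n_communities
        for c in self.assignment.values():
            counts[c - 1] += 1
        return counts

    def members(self, label: int) -> list:
        return [n for n, c in self.assignment.items() if c == label]

    def communities(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, []).append(n)
        return out

    def restricted_to(self, nodes: Iterable) -> "CommunityStructure":
        return CommunityStructure(
            assignment={n: self.assignment[n] for n in nodes}, method=self.method
        )


def modularity(network, structure: CommunityStructure) -> float:
    """Newman modularity Q = sum_c [ e_c/m - (d_c/2m)^2 ].

    ``e_c`` counts edges inside community c, ``d_c`` is the total degree of
    its members and ``m`` the number of edges in the graph.
    """
    g = _as_graph(network)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an empty edge set")
    assignment = structure.assignment
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"nodes absent from the partition: {missing[:5]!r}")
    n_comm = structure.n_communities
    e_c = np.zeros(n_comm)
    d_c = np.zeros(n_comm)
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            e_c[assignment[u] - 1] += 1
    for node, deg in g.degree:
        d_c[assignment[node] - 1] += deg
    return float(np.sum(e_c / m - (d_c / (2.0 * m)) ** 2))


# ---------------------------------------------------------------------------
# greedy agglomerative (fast-greedy) detection


def _greedy_component(g: nx.Graph, nodes: list) -> list[set]:
    """Greedy modularity agglomeration on one connected component.

    Among merges whose modularity gain ties within 1e-12 of the maximum the
    pair with the lexicographically smallest (min label, max label) is taken,
    where labels are the initial singleton indices in sorted node order.
    """
    sub = g.subgraph(nodes)
    m = sub.number_of_edges()
    order = sorted(nodes, key=str)
    idx = {n: i for i, n in enumerate(order)}

    # community state: members, total degree, inter-community edge weights
    members: dict[int, set] = {i: {n} for n, i in idx.items()}
    degree: dict[int, float] = {idx[n]: sub.degree(n) for n in order}
    links: dict[int, dict[int, float]] = {i: {} for i in members}
    for u, v in sub.edges:
        iu, iv = idx[u], idx[v]
        links[iu][iv] = links[iu].get(iv, 0) + 1
        links[iv][iu] = links[iv].get(iu, 0) + 1

    two_m = 2.0 * m
    while len(members) > 1:
        best = None
        best_dq = 0.0
        for a in members:
            for b, e_ab in links[a].items():
                if b <= a:
                    continue
                dq = e_ab / m - 2.0 * degree[a] * degree[b] / (two_m * two_m)
                if dq <= _DQ_TOL:
                    continue  # not a modularity increase
                if best is None or dq > best_dq + _DQ_TOL:
                    best, best_dq = (a, b), dq
                elif dq >= best_dq - _DQ_TOL and (a, b) < best:
                    best = (a, b)
        if best is None:
            break
        a, b = best
        members[a] |= members.pop(b)
        degree[a] += degree.pop(b)
        for c, w in links.pop(b).items():
            if c == a:
                continue
            links[c].pop(b, None)
            links[c][a] = links[c].get(a, 0) + w
            links[a][c] = links[a].get(c, 0) + w
        links[a].pop(b, None)
    return list(members.values())


def detect_greedy_agglomerative(network) -> CommunityStructure:
    """Fast-greedy modularity maximization, run per connected component."""
    g = _as_graph(network)
    _check_detectable(g)
    assignment: dict[Hashable, int] = {}
    label = 0
    for comp_nodes in _sorted_components(g):
        for group in _greedy_component(g, comp_nodes):
            label += 1
            for n in group:
                assignment[n] = label
    structure = CommunityStructure(assignment, method="greedy_agglomerative")
    structure.modularity = modularity(g, structure)
    return structure


# ---------------------------------------------------------------------------
# leading-eigenvector detection


def _leading_eig(bg: np.ndarray):
    """Leading eigenpair of a small symmetric matrix, sign-normalized."""
    n = bg.shape[0]
    if n <= 256:
        w, v = scipy.linalg.eigh(bg)
        lam, vec = w[-1], v[:, -1]
    else:  # iterative solver for large subgraphs
        try:
            w, v = scipy.sparse.linalg.eigsh(bg, k=1, which="LA")
        except scipy.sparse.linalg.ArpackNoConvergence as exc:  # pragma: no cover
            raise RuntimeError(
                f"eigen-solver failed to converge on a subgraph of {n} nodes"
            ) from exc
        lam, vec = w[0], v[:, 0]
    # deterministic sign: largest-|entry| component made positive
    pivot = int(np.argmax(np.abs(vec)))
    if vec[pivot] < 0:
        vec = -vec
    return lam, vec


def _le_component(g: nx.Graph, nodes: list) -> list[list]:
    sub = g.subgraph(nodes)
    order = sorted(nodes, key=str)
    idx = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v in sub.edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    k = a.sum(axis=1)
    m = sub.number_of_edges()
    b_full = a - np.outer(k, k) / (2.0 * m)

    groups: list[list[int]] = []

    def split(indices: np.ndarray) -> None:
        if indices.size <= 1:
            groups.append(indices.tolist())
            return
        bg = b_full[np.ix_(indices, indices)]
        bg = bg - np.diag(bg.sum(axis=1))
        lam, vec = _leading_eig(bg)
        if lam <= _EIG_TOL:
            groups.append(indices.tolist())
            return
        s = np.where(vec >= 0.0, 1.0, -1.0)
        s = _fine_tune_split(bg, s, m)
        if np.all(s == s[0]):
            groups.append(indices.tolist())
            return
        dq = float(s @ bg @ s) / (4.0 * m)
        if dq <= _DQ_TOL:
            groups.append(indices.tolist())
            return
        split(indices[s > 0])
        split(indices[s < 0])

    split(np.arange(len(order)))
    return [[order[i] for i in grp] for grp in groups]


def _fine_tune_split(bg: np.ndarray, s: np.ndarray, m: int) -> np.ndarray:
    """Kernighan-Lin-style vertex-move refinement of a proposed bisection.

    Repeated passes: every vertex is moved exactly once, each time choosing
    the move with the largest modularity change (ties to the smallest
    index), and the best prefix of the pass is kept when it improves the
    split.  This is the fine-tuning stage of the classical
    leading-eigenvector method; without it single misplaced vertices cannot
    be corrected by further bisection.
    """
    n = s.size
    s = s.copy()
    diag = np.diag(bg)
    for _ in range(50):  # passes; loop exits as soon as one fails to improve
        state = s.copy()
        bs = bg @ state
        moved = np.zeros(n, bool)
        cumulative = 0.0
        best_gain, best_prefix = 0.0, 0
        order: list[int] = []
        for step in range(n):
            gains = (diag - state * bs) / m
            gains[moved] = -np.inf
            v = int(np.argmin(np.where(gains == gains.max(), np.arange(n), n)))
            cumulative += gains[v]
            bs -= 2.0 * state[v] * bg[:, v]
            state[v] = -state[v]
            moved[v] = True
            order.append(v)
            if cumulative > best_gain + _DQ_TOL:
                best_gain, best_prefix = cumulative, step + 1
        if best_prefix == 0:
            break
        for v in order[:best_prefix]:
            s[v] = -s[v]
    return s


def detect_leading_eigenvector(network) -> CommunityStructure:
    """Recursive spectral bisection of the generalized modularity matrix."""
    g = _as_graph(network)
    _check_detectable(g)
    assignment: dict[Hashable, int] = {}
    label = 0
    for comp_nodes in _sorted_components(g):
        for group in _le_component(g, comp_nodes):
            label += 1
            for n in group:
                assignment[n] = label
    structure = CommunityStructure(assignment, method="leading_eigenvector")
    structure.modularity = modularity(g, structure)
    return structure


# ---------------------------------------------------------------------------


def _check_detectable(g: nx.Graph) -> None:
    if g.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    isolates = [n for n in g.nodes if g.degree(n) == 0]
    if isolates:
        raise ValueError(
            f"degree-0 nodes present (e.g. {isolates[0]!r}); remove isolates first"
        )


def _sorted_components(g: nx.Graph) -> list[list]:
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: str(c[0]))
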