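"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive explicit loops and full enumeration
so that they are independent of the (vectorized, log-space, quadrature-based)
implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netspill import CommunityStructure
from netspill.network import build_network


def make_network(edges, nodes=None, **kw):
    """Tiny helper: network from edge pairs with dummy records."""
    if nodes is None:
        nodes = sorted({v for e in edges for v in e})
    recs = [{"id": n, "treatment": 0, "outcome": 0} for n in nodes]
    return build_network(edges, recs, **kw)


@pytest.fixture
def two_triangles():
    return make_network(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    )


@pytest.fixture
def bridged_triangles():
    return make_network(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )


def planted_block_network(sizes, p_within, n_between, rng, p_between=None):
    """Dense blocks plus a fixed number (or probability) of between edges."""
    nodes, labels = [], {}
    for b, size in enumerate(sizes, start=1):
        for k in range(size):
            node = f"b{b}n{k:02d}"
            nodes.append(node)
            labels[node] = b
    edges = set()
    by_block = {}
    for n in nodes:
        by_block.setdefault(labels[n], []).append(n)
    for members in by_block.values():
        order = list(rng.permutation(members))
        for i in range(1, len(order)):
            edges.add(tuple(sorted((order[i], order[rng.integers(i)]))))
        for u, v in itertools.combinations(members, 2):
            if rng.random() < p_within:
                edges.add(tuple(sorted((u, v))))
    blocks = sorted(by_block)
    if p_between is not None:
        for bi, bj in itertools.combinations(blocks, 2):
            for u in by_block[bi]:
                for v in by_block[bj]:
                    if rng.random() < p_between:
                        edges.add(tuple(sorted((u, v))))
    else:
        for bi, bj in zip(blocks, blocks[1:]):
            for _ in range(n_between):
                u = by_block[bi][rng.integers(len(by_block[bi]))]
                v = by_block[bj][rng.integers(len(by_block[bj]))]
                edges.add(tuple(sorted((u, v))))
    net = make_network(sorted(edges), nodes=nodes)
    return net, CommunityStructure(labels)


# ---------------------------------------------------------------------------
# brute-force oracles


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_modularity_max(graph: nx.Graph):
    """Globally modularity-maximal partition by exhaustive enumeration."""
    nodes = sorted(graph.nodes, key=str)
    m = graph.number_of_edges()
    deg = dict(graph.degree)
    best_q, best = -np.inf, None
    for part in set_partitions(nodes):
        q = 0.0
        for block in part:
            bs = set(block)
            e_c = sum(1 for u, v in graph.edges if u in bs and v in bs)
            d_c = sum(deg[n] for n in block)
            q += e_c / m - (d_c / (2 * m)) ** 2
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best_q, best


def brute_group_mean(a, y, f, alpha, arm):
    """Naive loop evaluation of the community arm-specific IPW average."""
    n = len(a)
    total = 0.0
    for j in range(n):
        pi = 1.0
        for k in range(n):
            if k == j:
                continue
            pi *= alpha if a[k] == 1 else (1 - alpha)
        if a[j] == arm:
            total += pi * y[j]
    return total / (n * f)


def brute_group_marginal(a, y, f, alpha):
    n = len(a)
    pi = 1.0
    for k in range(n):
        pi *= alpha if a[k] == 1 else (1 - alpha)
    return pi * sum(y) / (n * f)


def brute_voi(labels1, labels2):
    """Direct conditional-entropy evaluation of the normalized VOI."""
    n = len(labels1)
    pairs = list(zip(labels1, labels2))
    h_cond_12 = 0.0
    h_cond_21 = 0.0
    for c1 in set(labels1):
        for c2 in set(labels2):
            p12 = pairs.count((c1, c2)) / n
            if p12 == 0:
                continue
            p1 = labels1.count(c1) / n
            p2 = labels2.count(c2) / n
            h_cond_12 -= p12 * math.log(p12 / p2)
            h_cond_21 -= p12 * math.log(p12 / p1)
    return (h_cond_12 + h_cond_21) / math.log(n)
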