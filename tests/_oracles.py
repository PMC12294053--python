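"""Independent reference computations used to check the implementation.

Each oracle deliberately takes a different algorithmic route from the code
under test: exhaustive enumeration instead of dynamic programming, matrix
exponentials instead of closed forms, term-by-term summation instead of
library tail functions, least-squares topology scans instead of
agglomeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


# --- affine-gap global alignment by exhaustive path enumeration -------------


def brute_force_global_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Max score over every monotone alignment, scored with affine gaps.

    Exponential enumeration; only for short strings (<= ~8 bp).
    """
    best = [-math.inf]

    def step(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] not in "N") else mismatch
            step(i + 1, j + 1, score + s, "D")
        if i < len(a):
            g = gap_extend if prev == "U" else gap_open
            step(i + 1, j, score + g, "U")
        if j < len(b):
            g = gap_extend if prev == "L" else gap_open
            step(i, j + 1, score + g, "L")

    step(0, 0, 0.0, "")
    return best[0]


# --- unrooted topology enumeration + least-squares branch fitting -----------


def enumerate_topologies(labels: list[str]):
    """All unrooted leaf-labeled binary topologies as edge-list dicts.

    Nodes: leaf labels (str) and internal ints.  Built by inserting leaves
    one at a time on every edge (3 -> 15 -> 105 ... topologies).
    """
    assert len(labels) >= 3
    first = {"edges": [(labels[0], 0), (labels[1], 0), (labels[2], 0)], "next": 1}
    trees = [first]
    for leaf in labels[3:]:
        new_trees = []
        for tree in trees:
            for k, (u, v) in enumerate(tree["edges"]):
                node = tree["next"]
                edges = [e for i, e in enumerate(tree["edges"]) if i != k]
                edges += [(u, node), (node, v), (leaf, node)]
                new_trees.append({"edges": edges, "next": node + 1})
        trees = new_trees
    return [t["edges"] for t in trees]


def _paths(edges, labels):
    """Leaf-pair -> set of edge indices on the connecting path."""
    adj: dict = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    def path(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, used = stack.pop()
            if node == dst:
                return used
            for nbr, k in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, node, used + [k]))
        raise RuntimeError("disconnected tree")

    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[(a, b)] = path(a, b)
    return out


def least_squares_topology(labels: list[str], D: np.ndarray):
    """Best-fitting topology by OLS branch lengths over all topologies.

    Returns (bipartitions, rss) of the minimum-RSS topology.  For an
    additive matrix the generating topology fits with RSS ~ 0.
    """
    idx = {l: i for i, l in enumerate(labels)}
    best = None
    for edges in enumerate_topologies(labels):
        paths = _paths(edges, labels)
        A = np.zeros((len(paths), len(edges)))
        y = np.zeros(len(paths))
        for r, ((a, b), eids) in enumerate(paths.items()):
            A[r, eids] = 1.0
            y[r] = D[idx[a], idx[b]]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if best is None or rss < best[1]:
            best = (tree_bipartitions(edges, labels), rss)
    return best


def tree_bipartitions(edges, labels) -> set[frozenset]:
    """Canonical non-trivial bipartitions of an edge-list topology."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    all_leaves = frozenset(labels)
    bips = set()
    for u, v in edges:
        # leaves on the u side when edge (u, v) is cut
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side = frozenset(side)
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return bips


def random_additive_matrix(labels: list[str], rng: np.random.Generator):
    """Random binary topology with random lengths and its path-distance matrix."""
    edges = enumerate_topologies(labels)[0]
    # randomize: rebuild by random insertion order / attachment
    base = list(labels)
    rng.shuffle(base)
    tree = {"edges": [(base[0], 0), (base[1], 0), (base[2], 0)], "next": 1}
    for leaf in base[3:]:
        k = int(rng.integers(len(tree["edges"])))
        u, v = tree["edges"].pop(k)
        node = tree["next"]
        tree["edges"] += [(u, node), (node, v), (leaf, node)]
        tree["next"] = node + 1
    edges = tree["edges"]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _paths(edges, labels)
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    D = np.zeros((n, n))
    for (a, b), eids in paths.items():
        d = float(lengths[eids].sum())
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = d
    return D, tree_bipartitions(edges, labels)


# --- K2P likelihood by internal-state enumeration and matrix exponential ----


def k2p_prob_matrix_expm(t: float, kappa: float = 2.0) -> np.ndarray:
    """P(t) via expm of the normalized K2P rate matrix (independent route)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    Q = np.full((4, 4), beta)
    for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):
        Q[a, b] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return expm(Q * t)


def brute_force_k2p_loglik(tree, alignment_rows: dict[str, str], kappa: float = 2.0) -> float:
    """Sum over all internal-state assignments on a (small) dendropy tree."""
    code = {c: i for i, c in enumerate("ACGT")}
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    L = len(next(iter(alignment_rows.values())))
    logL = 0.0
    for site in range(L):
        total = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, states)}
            for lf in leaves:
                assign[id(lf)] = code[alignment_rows[lf.taxon.label][site]]
            prob = 0.25  # root state prior
            for node in nodes:
                if node.parent_node is None:
                    continue
                P = k2p_prob_matrix_expm(node.edge.length or 0.0, kappa)
                prob *= P[assign[id(node.parent_node)], assign[id(node)]]
            total += prob
        logL += math.log(total)
    return logL


# --- Poisson upper tail by term summation -----------------------------------


def poisson_upper_tail(count: int, lam: float) -> float:
    """P(X >= count) by direct pmf summation of the complement."""
    if count <= 0:
        return 1.0
    term = math.exp(-lam)
    acc = [term]
    for i in range(1, count):
        term = term * lam / i
        acc.append(term)
    return 1.0 - math.fsum(acc)
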