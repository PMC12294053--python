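"""Distance trees, bootstrap support, K2P likelihood, and incongruence scan.

Trees are built by neighbor joining on K2P distances (the desk-scale
stand-in for a full maximum-likelihood search at the same substitution
model), optionally refined by nearest-neighbor-interchange hill climbing
under a K2P pruning likelihood with fixed transition/transversion ratio.
The horizontal-transfer signal is phylogenetic incongruence: a leaf whose
nearest neighbors in the tree (by patristic distance) belong predominantly
to a foreign taxon group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .align import Alignment
from .distances import DistanceMatrix, distance_matrix

# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _format_length(x: float) -> str:
    return f"{max(x, 0.0):.10g}"


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representative ids (each cluster is represented by its
    smallest leaf id), so the result does not depend on input order.
    Negative pendant branch lengths are clamped to zero with the deficit
    moved to the sibling edge, preserving the joined pair's mutual distance.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries; cap saturation first")
    D = dm.d.astype(float).copy()
    labels = list(dm.ids)  # newick fragments
    reps = list(dm.ids)
    while len(labels) > 3:
        size = len(labels)
        r = D.sum(axis=1)
        Q = (size - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-9))
        best = min(
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i, j in candidates
            if i < j
        )
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (size - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li = max(li + lj, 0.0)
            lj = 0.0
        new_label = f"({labels[i]}:{_format_length(li)},{labels[j]}:{_format_length(lj)})"
        new_rep = min(reps[i], reps[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(size) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        labels = [labels[k] for k in keep] + [new_label]
        reps = [reps[k] for k in keep] + [new_rep]
    # final trifurcation via the three-point formulas
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    newick = (
        f"({labels[0]}:{_format_length(la)},{labels[1]}:{_format_length(lb)},"
        f"{labels[2]}:{_format_length(lc)});"
    )
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Canonical leaf-set bipartition keyed by internal-edge id.

    The canonical form is the min (by sorted tuple) of the two leaf sets,
    so keys are comparable across differently rooted trees.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[int, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if not other:
            continue
        key = min(side, other, key=lambda s: tuple(sorted(s)))
        out[id(node)] = key
    return out


def _resample_columns(alignment: Alignment, cols: np.ndarray) -> Alignment:
    mats = {rid: np.frombuffer(row.encode(), dtype=np.uint8) for rid, row in alignment.rows}
    return Alignment(
        rows=[(rid, mats[rid][cols].tobytes().decode()) for rid in alignment.ids]
    )


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    method: str = "k2p",
    saturation_cap: float = 5.0,
) -> dendropy.Tree:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement per replicate (replicate r uses
    the seed sequence ``[seed, r]``), the tree is rebuilt, and each original
    internal bipartition's support is the percentage of replicates that
    contain it.  Supports are stored as internal node labels.
    """
    if alignment.length < 1:
        raise ValueError("alignment must have at least one column")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_tree = neighbor_joining(distance_matrix(alignment, method, saturation_cap))
    base_bips = _bipartitions(base_tree)
    counts = {key: 0 for key in base_bips.values()}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, alignment.length, size=alignment.length)
        rep_aln = _resample_columns(alignment, cols)
        rep_tree = neighbor_joining(distance_matrix(rep_aln, method, saturation_cap))
        rep_keys = set(_bipartitions(rep_tree).values())
        for key in counts:
            if key in rep_keys:
                counts[key] += 1
    for node in base_tree.preorder_node_iter():
        key = base_bips.get(id(node))
        if key is not None:
            node.label = f"{100.0 * counts[key] / n_reps:g}"
    return base_tree


# ---------------------------------------------------------------------------
# K2P likelihood (Felsenstein pruning) and NNI refinement
# ---------------------------------------------------------------------------


def k2p_transition_matrix(d: float, kappa: float = 2.0) -> np.ndarray:
    """K2P substitution probability matrix for branch length d (subs/site).

    Base order A, C, G, T; transitions are A<->G and C<->T; kappa is the
    transition/transversion *rate* ratio.
    """
    d = max(float(d), 0.0)
    e1 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    same = 0.25 + 0.25 * e1 + 0.5 * e2
    ts = 0.25 + 0.25 * e1 - 0.5 * e2
    tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), tv)
    np.fill_diagonal(P, same)
    for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):
        P[a, b] = ts
    return P


class _UnrootedTree:
    """Light adjacency representation used for likelihood and NNI moves."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.lengths: dict[frozenset, float] = {}
        self.leaf_label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.leaf_label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.lengths[frozenset((u, v))] = max(float(length), 0.0)

    def remove_edge(self, u: int, v: int) -> float:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        return self.lengths.pop(frozenset((u, v)))

    def copy(self) -> "_UnrootedTree":
        t = _UnrootedTree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.lengths = dict(self.lengths)
        t.leaf_label = dict(self.leaf_label)
        t._next = self._next
        return t

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            tuple(sorted(e))
            for e in self.lengths
            if all(len(self.adj[v]) > 1 for v in e)
        ]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "_UnrootedTree":
        t = cls()
        node_map: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else None
            node_map[id(node)] = t.new_node(label)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length or 0.0
                t.add_edge(node_map[id(node.parent_node)], node_map[id(node)], length)
        return t

    def to_dendropy(self) -> dendropy.Tree:
        root = next((n for n in self.adj if len(self.adj[n]) > 1), min(self.adj))

        def build(node: int, parent: Optional[int]) -> str:
            children = [v for v in self.adj[node] if v != parent]
            if not children:
                return self.leaf_label[node]
            parts = []
            for child in children:
                length = self.lengths[frozenset((node, child))]
                parts.append(f"{build(child, node)}:{length:.10g}")
            return "(" + ",".join(parts) + ")"

        return dendropy.Tree.get(
            data=build(root, None) + ";", schema="newick", preserve_underscores=True
        )


def _leaf_partials(alignment: Alignment) -> dict[str, np.ndarray]:
    from .align import encode_residues

    partials = {}
    for rid, row in alignment.rows:
        codes = encode_residues(row.replace("-", "N"))
        part = np.zeros((4, len(codes)))
        known = codes < 4
        part[:, ~known] = 1.0  # missing data: uninformative
        part[codes[known], np.nonzero(known)[0]] = 1.0
        partials[rid] = part
    return partials


def _tree_loglik(
    tree: _UnrootedTree, partials: dict[str, np.ndarray], kappa: float
) -> float:
    root = next((n for n in tree.adj if len(tree.adj[n]) > 1), min(tree.adj))

    def partial_from(node: int, parent: int) -> np.ndarray:
        """Conditional likelihood at ``node`` for the subtree away from parent."""
        if node in tree.leaf_label:
            return partials[tree.leaf_label[node]]
        below = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            P = k2p_transition_matrix(tree.lengths[frozenset((node, child))], kappa)
            contrib = P @ partial_from(child, node)
            below = contrib if below is None else below * contrib
        return below

    total = None
    for child in tree.adj[root]:
        P = k2p_transition_matrix(tree.lengths[frozenset((root, child))], kappa)
        contrib = P @ partial_from(child, root)
        total = contrib if total is None else total * contrib
    if root in tree.leaf_label:
        total = total * partials[tree.leaf_label[root]]
    site_lik = 0.25 * total.sum(axis=0)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.log(site_lik).sum())


def k2p_likelihood(tree: dendropy.Tree, alignment: Alignment, kappa: float = 2.0) -> float:
    """Log-likelihood of the alignment on the tree under K2P (fixed kappa).

    Felsenstein pruning with equal base frequencies; gap/N columns act as
    missing data for that leaf.  Leaves of the tree must be a subset of the
    alignment rows.
    """
    if alignment.length < 1:
        raise ValueError("alignment must have at least one column")
    partials = _leaf_partials(alignment)
    t = _UnrootedTree.from_dendropy(tree)
    for label in t.leaf_label.values():
        if label not in partials:
            raise ValueError(f"tree leaf {label!r} not present in alignment")
    return _tree_loglik(t, partials, kappa)


def _optimize_lengths(
    tree: _UnrootedTree, partials: dict[str, np.ndarray], kappa: float, sweeps: int = 1
) -> float:
    best = _tree_loglik(tree, partials, kappa)
    for _ in range(sweeps):
        for edge in sorted(tree.lengths, key=lambda e: tuple(sorted(e))):
            def neg(x: float, edge=edge) -> float:
                tree.lengths[edge] = x
                return -_tree_loglik(tree, partials, kappa)

            res = minimize_scalar(
                neg, bounds=(1e-8, 10.0), method="bounded", options={"xatol": 1e-7}
            )
            tree.lengths[edge] = float(res.x)
        best = _tree_loglik(tree, partials, kappa)
    return best


def _nni_alternatives(tree: _UnrootedTree, u: int, v: int) -> list[_UnrootedTree]:
    """The two NNI rearrangements across internal edge (u, v)."""
    b = sorted(x for x in tree.adj[u] if x != v)[-1]
    alternatives = []
    for c in sorted(x for x in tree.adj[v] if x != u):
        t = tree.copy()
        lb = t.remove_edge(u, b)
        lc = t.remove_edge(v, c)
        t.add_edge(u, c, lc)
        t.add_edge(v, b, lb)
        alternatives.append(t)
    return alternatives


def nni_refine(
    tree: dendropy.Tree,
    alignment: Alignment,
    max_rounds: int = 10,
    kappa: float = 2.0,
    tol: float = 1e-6,
) -> dendropy.Tree:
    """Hill-climb over nearest-neighbor interchanges under K2P likelihood.

    Branch lengths are re-optimized (bounded Brent per edge) for every
    candidate topology; the search stops when no move improves the
    log-likelihood by more than ``tol`` or after ``max_rounds`` rounds.
    """
    partials = _leaf_partials(alignment)
    current = _UnrootedTree.from_dendropy(tree)
    current_lik = _optimize_lengths(current, partials, kappa, sweeps=2)
    for _ in range(max_rounds):
        best_alt, best_lik = None, current_lik
        for u, v in current.internal_edges():
            for alt in _nni_alternatives(current, u, v):
                lik = _optimize_lengths(alt, partials, kappa, sweeps=1)
                if lik > best_lik + tol:
                    best_alt, best_lik = alt, lik
        if best_alt is None:
            break
        current, current_lik = best_alt, best_lik
    return current.to_dendropy()


# ---------------------------------------------------------------------------
# Incongruence scan
# ---------------------------------------------------------------------------


@dataclass
class IncongruenceReport:
    """Neighborhood composition of one leaf in the tree.

    ``flagged`` is True when the leaf's own group holds a strict minority
    (< 50%) of its m nearest leaves by patristic distance — the tree-based
    formalization of "clusters with a foreign clade".
    ``nearest_foreign_distance`` (patristic distance to the closest leaf of
    any other group) lets callers distinguish a leaf *nested inside* a
    foreign clade from one that is merely isolated: a lone diverged leaf
    also has a minority neighborhood, but sits far from everything.
    """

    leaf_id: str
    group: str
    neighbor_groups: dict[str, int]
    m: int
    own_fraction: float
    flagged: bool
    nearest_foreign_distance: float = math.inf


def incongruence_scan(
    tree: dendropy.Tree, groups: dict[str, str], m: int = 3
) -> list[IncongruenceReport]:
    """Flag leaves placed among a foreign taxon group.

    Invariant to leaf input order and to re-rooting (patristic distances are
    root-independent).  Reports are sorted by own-group fraction ascending,
    then leaf id.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unlabeled = [l for l in leaves if l not in groups]
    if unlabeled:
        raise ValueError(f"leaves without group labels: {unlabeled}")
    if m < 1 or m >= len(leaves):
        raise ValueError(f"neighborhood size m={m} must be in [1, n_leaves)")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    reports = []
    for leaf in leaves:
        dists = sorted(
            (pdm.patristic_distance(taxa[leaf], taxa[other]), other)
            for other in leaves
            if other != leaf
        )
        neighbors = [other for _, other in dists[:m]]
        comp: dict[str, int] = {}
        for other in neighbors:
            comp[groups[other]] = comp.get(groups[other], 0) + 1
        own = comp.get(groups[leaf], 0) / m
        foreign = min(
            (d for d, other in dists if groups[other] != groups[leaf]),
            default=math.inf,
        )
        reports.append(
            IncongruenceReport(
                leaf_id=leaf,
                group=groups[leaf],
                neighbor_groups=comp,
                m=m,
                own_fraction=own,
                flagged=own < 0.5,
                nearest_foreign_distance=foreign,
            )
        )
    reports.sort(key=lambda r: (r.own_fraction, r.leaf_id))
    return reports


def write_incongruence_tsv(reports: Sequence[IncongruenceReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("leaf_id\tgroup\town_fraction\tflagged\tneighborhood\n")
        for r in reports:
            comp = ",".join(f"{g}:{c}" for g, c in sorted(r.neighbor_groups.items()))
            fh.write(f"{r.leaf_id}\t{r.group}\t{r.own_fraction:.3f}\t{int(r.flagged)}\t{comp}\n")
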