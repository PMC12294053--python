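import math

import dendropy
import numpy as np
import pytest

from hgtscreen.align import Alignment
from hgtscreen.distances import DistanceMatrix, distance_matrix
from hgtscreen.phylo import (
    bootstrap_support,
    incongruence_scan,
    k2p_likelihood,
    k2p_transition_matrix,
    neighbor_joining,
    nni_refine,
)
from hgtscreen.simulate import mutate_k2p, random_sequence

from _oracles import (
    brute_force_k2p_loglik,
    k2p_prob_matrix_expm,
    least_squares_topology,
    random_additive_matrix,
    tree_bipartitions,
)


def _dm(ids, d):
    d = np.asarray(d, dtype=float)
    z = np.zeros_like(d, dtype=bool)
    return DistanceMatrix(list(ids), d, z, z)


def _newick_bipartitions(tree):
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = labels - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return bips


def test_nj_three_taxon_pendant_lengths():
    tree = neighbor_joining(_dm("ABC", [[0, 2, 3], [2, 0, 4], [3, 4, 0]]))
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})


@pytest.mark.parametrize("n_taxa,seed", [(5, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
def test_nj_recovers_additive_topology(n_taxa, seed):
    labels = [f"T{i}" for i in range(n_taxa)]
    D, true_bips = random_additive_matrix(labels, np.random.default_rng(seed))
    tree = neighbor_joining(_dm(labels, D))
    assert _newick_bipartitions(tree) == true_bips
    # and the least-squares enumeration oracle agrees
    ls_bips, rss = least_squares_topology(labels, D)
    assert rss < 1e-18
    assert ls_bips == true_bips


def test_nj_all_equal_distances_resolved_with_zero_internal_edges():
    n = 5
    D = np.ones((n, n)) - np.eye(n)
    tree = neighbor_joining(_dm([f"T{i}" for i in range(n)], D))
    internal = [
        e.length
        for e in tree.preorder_edge_iter()
        if e.head_node is not None
        and not e.head_node.is_leaf()
        and e.tail_node is not None
    ]
    assert all(abs(l) < 1e-12 for l in internal)


def test_nj_order_invariance():
    labels = [f"T{i}" for i in range(6)]
    D, _ = random_additive_matrix(labels, np.random.default_rng(9))
    tree1 = neighbor_joining(_dm(labels, D))
    perm = [3, 1, 5, 0, 4, 2]
    tree2 = neighbor_joining(
        _dm([labels[i] for i in perm], D[np.ix_(perm, perm)])
    )
    assert _newick_bipartitions(tree1) == _newick_bipartitions(tree2)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(_dm("AB", [[0, 1], [1, 0]]))


def test_nj_matches_dendropy_reference_on_random_matrix():
    # independent cross-check against dendropy's own NJ implementation
    rng = np.random.default_rng(4)
    labels = [f"T{i}" for i in range(6)]
    D, _ = random_additive_matrix(labels, rng)
    tree = neighbor_joining(_dm(labels, D))
    pdm_csv = ["," + ",".join(labels)]
    for i, l in enumerate(labels):
        pdm_csv.append(l + "," + ",".join(str(x) for x in D[i]))
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO("\n".join(pdm_csv)))
    ref = pdm.nj_tree()
    assert _newick_bipartitions(tree) == _newick_bipartitions(ref)


def test_bootstrap_clean_split_gets_full_support(rng):
    base = random_sequence(rng, 150)
    other = mutate_k2p(base, 0.8, rng=rng)
    aln = Alignment(rows=[("A1", base), ("A2", base), ("B1", other), ("B2", other)])
    tree = bootstrap_support(aln, n_reps=100, seed=11)
    supports = [
        float(n.label)
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None and n.label
    ]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_single_replicate_support_binary(rng):
    rows = [(f"L{i}", random_sequence(np.random.default_rng(i), 60)) for i in range(5)]
    tree = bootstrap_support(Alignment(rows=rows), n_reps=1, seed=0)
    supports = [
        float(n.label)
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None and n.label
    ]
    assert supports and set(supports) <= {0.0, 100.0}


def test_bootstrap_taxon_order_invariant(rng):
    rows = [(f"L{i}", random_sequence(np.random.default_rng(i + 7), 80)) for i in range(5)]
    t1 = bootstrap_support(Alignment(rows=rows), n_reps=20, seed=5)
    t2 = bootstrap_support(Alignment(rows=rows[::-1]), n_reps=20, seed=5)

    def support_map(tree):
        out = {}
        labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        for n in tree.preorder_node_iter():
            if n.is_leaf() or n.parent_node is None or not n.label:
                continue
            side = frozenset(lf.taxon.label for lf in n.leaf_iter())
            key = min(side, labels - side, key=lambda s: tuple(sorted(s)))
            out[key] = float(n.label)
        return out

    assert support_map(t1) == support_map(t2)


def test_k2p_transition_matrix_agrees_with_expm():
    for d in (0.0, 0.1, 0.5, 2.0):
        for kappa in (1.0, 2.0, 4.0):
            assert np.allclose(
                k2p_transition_matrix(d, kappa), k2p_prob_matrix_expm(d, kappa), atol=1e-10
            )


def test_two_identical_leaves_likelihood_limit():
    tree = dendropy.Tree.get(data="(A:0.00000001,B:0.00000001);", schema="newick")
    aln = Alignment(rows=[("A", "ACGTACGTAC"), ("B", "ACGTACGTAC")])
    assert k2p_likelihood(tree, aln) == pytest.approx(10 * math.log(0.25), abs=1e-5)


@pytest.mark.parametrize(
    "newick,n_leaves",
    [
        ("(A:0.12,B:0.3,C:0.21);", 3),
        ("((A:0.1,B:0.25):0.15,C:0.3,D:0.05);", 4),
    ],
)
def test_pruning_matches_state_enumeration_oracle(newick, n_leaves, rng):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rows = {
        label: random_sequence(np.random.default_rng(i + 1), 20)
        for i, label in enumerate("ABCD"[:n_leaves])
    }
    aln = Alignment(rows=list(rows.items()))
    mine = k2p_likelihood(tree, aln)
    oracle = brute_force_k2p_loglik(tree, rows)
    assert mine == pytest.approx(oracle, abs=1e-9)


def test_nni_leaves_consistent_tree_unchanged(rng):
    anc = random_sequence(rng, 400)
    a = mutate_k2p(anc, 0.03, rng=rng)
    b = mutate_k2p(anc, 0.03, rng=rng)
    anc2 = mutate_k2p(anc, 0.5, rng=rng)
    c = mutate_k2p(anc2, 0.03, rng=rng)
    d = mutate_k2p(anc2, 0.03, rng=rng)
    aln = Alignment(rows=[("A", a), ("B", b), ("C", c), ("D", d)])
    nj = neighbor_joining(distance_matrix(aln))
    refined = nni_refine(nj, aln, max_rounds=3)
    assert _newick_bipartitions(refined) == _newick_bipartitions(nj)
    assert k2p_likelihood(refined, aln) >= k2p_likelihood(nj, aln) - 1e-6


def test_nni_repairs_a_wrong_topology(rng):
    anc = random_sequence(rng, 400)
    a = mutate_k2p(anc, 0.03, rng=rng)
    b = mutate_k2p(anc, 0.03, rng=rng)
    anc2 = mutate_k2p(anc, 0.5, rng=rng)
    c = mutate_k2p(anc2, 0.03, rng=rng)
    d = mutate_k2p(anc2, 0.03, rng=rng)
    aln = Alignment(rows=[("A", a), ("B", b), ("C", c), ("D", d)])
    bad = dendropy.Tree.get(data="((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);", schema="newick")
    refined = nni_refine(bad, aln, max_rounds=5)
    assert _newick_bipartitions(refined) == {frozenset({"A", "B"})}


def test_incongruence_flags_misplaced_leaf():
    tree = dendropy.Tree.get(
        data="((A1:1,A2:1):1,(B1:1,(B2:1,A3:1):1):1);", schema="newick"
    )
    groups = {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B"}
    reports = incongruence_scan(tree, groups, m=2)
    flagged = [r.leaf_id for r in reports if r.flagged]
    assert flagged == ["A3"]
    assert reports[0].leaf_id == "A3"  # sorted by own fraction ascending
    assert sum(reports[0].neighbor_groups.values()) == 2


def test_incongruence_all_same_group_none_flagged():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    reports = incongruence_scan(tree, {l: "G" for l in "ABCD"}, m=2)
    assert not any(r.flagged for r in reports)


def test_incongruence_invariant_to_rerooting():
    nwk = "((A1:1,A2:1):1,(B1:1,(B2:1,A3:1):1):1);"
    groups = {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B"}
    t1 = dendropy.Tree.get(data=nwk, schema="newick")
    t2 = dendropy.Tree.get(data=nwk, schema="newick")
    leaf = [l for l in t2.leaf_node_iter() if l.taxon.label == "B1"][0]
    t2.reroot_at_edge(leaf.edge, update_bipartitions=False)
    r1 = {(r.leaf_id, r.flagged) for r in incongruence_scan(t1, groups, m=2)}
    r2 = {(r.leaf_id, r.flagged) for r in incongruence_scan(t2, groups, m=2)}
    assert r1 == r2


def test_incongruence_m_bounds():
    tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
    with pytest.raises(ValueError):
        incongruence_scan(tree, {l: "G" for l in "ABC"}, m=3)
    with pytest.raises(ValueError):
        incongruence_scan(tree, {"A": "G", "B": "G"}, m=1)
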