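import numpy as np
import dendropy
import pytest
from hypothesis import given, settings, strategies as st

import scoperon as sp
from scoperon.seqio import OperonRecord, Region, Source
from scoperon.placement_core import (
    InsufficientOverlap,
    _fit_edge,
    _query_leaf_distances,
    _workspace,
    distance_matrix,
    edge_path_distance,
)


def brute_force_place(aq, refdb):
    """Independent oracle: bounded linear least squares per edge (scipy),
    same criterion as the placement engine but solved by a different
    optimiser; returns (edge_id, score)."""
    from scipy.optimize import lsq_linear

    ws = _workspace(refdb)
    d, usable = _query_leaf_distances(aq.encoded(), ws, refdb.trim_mask)
    obs = d[usable]
    w = 1.0 / np.maximum(obs, 1e-3) ** 2
    sw = np.sqrt(w)
    best = (np.inf, None)
    for node in ws.edges:
        b = ws.branch_length(node)
        inside = ws.inmask[node][usable]
        a = np.where(inside, ws.full[node][usable], ws.full[node.parent_node][usable] + b)
        s = np.where(inside, 1.0, -1.0)
        y = obs - a
        A = np.column_stack([np.ones_like(s), s])
        res = lsq_linear(
            A * sw[:, None], y * sw, bounds=([0.0, 0.0], [np.inf, max(b, 1e-12)])
        )
        rss = float(res.cost * 2)
        if rss < best[0] - 1e-12:
            best = (rss, node.label)
    return best[1], best[0]


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0.0), ("ACGT", "AGGT", 0.25), ("AC-T", "ACGT", 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert sp.pairwise_distance(a, b, min_overlap=3) == expected

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlap):
            sp.pairwise_distance("A---", "ACGT", min_overlap=3)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT-", min_size=20, max_size=60), st.data())
    def test_symmetric_bounded_zero_on_self(self, a, data):
        b = data.draw(st.text(alphabet="ACGT-", min_size=len(a), max_size=len(a)))
        try:
            dab = sp.pairwise_distance(a, b, min_overlap=1)
        except InsufficientOverlap:
            return
        assert dab == sp.pairwise_distance(b, a, min_overlap=1)
        assert 0.0 <= dab <= 1.0
        if a == b:
            assert dab == 0.0


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)); pairwise path lengths
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        tree = sp.nj_tree(D, ["A", "B", "C", "D"])
        assert _path_matrix(tree, ["A", "B", "C", "D"]) == pytest.approx(D, abs=1e-8)

    def test_three_taxon_closed_form(self):
        # d(A,B)=2, d(A,C)=3, d(B,C)=5 -> a=0, b=2, c=3 from the star equations
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = sp.nj_tree(D, ["A", "B", "C"])
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            sp.nj_tree(D, ["A", "B", "C"])

    def test_low_divergence_alignment_recovers_true_topology(self):
        params = sp.SimParams(n_ref_taxa=16, birth_rate=50.0, seed=3)
        refdb, _ = sp.simulate_reference(params)
        D, labels = distance_matrix(refdb.alignment, mask=refdb.trim_mask)
        rec = sp.nj_tree(D, labels)
        assert _rf(refdb.tree, rec) == 0


def _path_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                M[i, j] = pdm.patristic_distance(tax[labels[i]], tax[labels[j]])
    return M


def _rf(a, b):
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=sp.write_newick(a), schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=sp.write_newick(b), schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


class TestAlignment:
    def test_reference_row_aligns_to_itself(self, small_ref):
        refdb, _ = small_ref
        leaf = refdb.leaf_ids[0]
        rec = OperonRecord(
            id="self", sequence=refdb.alignment[leaf].replace("-", ""), source=Source.OTU
        )
        aq = sp.align_to_reference(rec, refdb)
        assert aq.states == refdb.alignment[leaf]

    def test_too_short_query_rejected(self, small_ref):
        refdb, _ = small_ref
        with pytest.raises(ValueError, match="too short"):
            sp.align_to_reference(
                OperonRecord(id="tiny", sequence="ACGTACGTAC"), refdb
            )

    def test_keeplength_width_for_queries_with_insertions(self, default_ref):
        params, refdb, truth = default_ref
        p = sp.SimParams(n_queries=10, insertion_rate=0.01, seed=9)
        queries, _ = sp.simulate_queries(refdb, sp.SimTruth(seed=9), p)
        r18 = refdb.restrict_to_regions([Region.SSU18S])
        for q in queries:
            assert len(sp.align_to_reference(q, r18).states) == r18.width

    def test_true_homology_recovered(self, default_ref):
        # clean descendant without insertions: aligned states must sit on
        # the parent's columns almost everywhere
        params, refdb, truth = default_ref
        p = sp.SimParams(n_queries=5, insertion_rate=0.0, seed=13)
        r18 = refdb.restrict_to_regions([Region.SSU18S])
        queries, t = sp.simulate_queries(refdb, sp.SimTruth(seed=13), p)
        for q in queries:
            if q.id not in t.clean_parent:
                continue
            aq = sp.align_to_reference(q, r18)
            parent_row = r18.alignment[t.clean_parent[q.id]]
            same = sum(
                1 for a, b in zip(aq.states, parent_row) if a != "-" and b != "-"
            )
            assert same / len(q.sequence) >= 0.95


class TestPlacement:
    def test_self_placement_on_own_terminal_edge(self, small_ref):
        refdb, _ = small_ref
        for leaf in refdb.leaf_ids[:4]:
            rec = OperonRecord(
                id="q", sequence=refdb.alignment[leaf].replace("-", ""), source=Source.OTU
            )
            pl = sp.place_query(sp.align_to_reference(rec, refdb), refdb)
            assert pl.edge_id == leaf
            # numerically zero: far below the 1/W p-distance resolution
            assert pl.pendant_length == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, small_ref):
        refdb, truth = small_ref
        p = sp.SimParams(n_queries=10, seed=21)
        queries, _ = sp.simulate_queries(refdb, sp.SimTruth(seed=21), p)
        for q in queries:
            aq = sp.align_to_reference(q, refdb)
            pl = sp.place_query(aq, refdb)
            edge, score = brute_force_place(aq, refdb)
            assert pl.edge_id == edge
            assert pl.score == pytest.approx(score, rel=1e-4, abs=1e-9)

    def test_clean_queries_land_on_or_next_to_true_branch(self, default_ref):
        params, refdb, truth = default_ref
        p = sp.SimParams(n_queries=100, chimera_fraction=0.0,
                         longbranch_fraction=0.0, seed=17)
        r18 = refdb.restrict_to_regions([Region.SSU18S])
        queries, t = sp.simulate_queries(refdb, sp.SimTruth(seed=17), p)
        hits = 0
        for q in queries:
            pl = sp.place_query(sp.align_to_reference(q, r18), r18)
            if edge_path_distance(r18, pl.edge_id, t.clean_parent[q.id]) <= 1:
                hits += 1
        assert hits >= 90

    def test_fit_edge_matches_scipy_on_random_inputs(self):
        from scipy.optimize import lsq_linear

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 20)
            y = rng.normal(0, 0.05, n)
            s = rng.choice([-1.0, 1.0], n)
            b = float(rng.uniform(0, 0.2))
            w = rng.uniform(0.5, 2.0, n)
            rss, p, x = _fit_edge(y, s, b, w)
            sw = np.sqrt(w)
            A = np.column_stack([np.ones(n), s])
            res = lsq_linear(A * sw[:, None], y * sw,
                             bounds=([0, 0], [np.inf, max(b, 1e-12)]))
            assert rss == pytest.approx(2 * res.cost, rel=1e-6, abs=1e-12)


class TestBootstrap:
    def test_identical_query_fully_supported(self, small_ref):
        refdb, _ = small_ref
        leaf = refdb.leaf_ids[2]
        rec = OperonRecord(
            id="q", sequence=refdb.alignment[leaf].replace("-", ""), source=Source.OTU
        )
        aq = sp.align_to_reference(rec, refdb)
        assert sp.bootstrap_support(aq, refdb, n_reps=10, seed=1) == 1.0

    def test_deterministic_for_fixed_seed(self, symmetric_quartet):
        refdb, query = symmetric_quartet
        aq = sp.align_to_reference(query, refdb)
        a = sp.bootstrap_support(aq, refdb, n_reps=50, seed=5)
        b = sp.bootstrap_support(aq, refdb, n_reps=50, seed=5)
        assert a == b

    def test_boundary_query_near_half_support(self, symmetric_quartet):
        # query carries exactly balanced derived sites from the two cherry
        # members, so column resampling flips the winning terminal edge
        refdb, query = symmetric_quartet
        aq = sp.align_to_reference(query, refdb)
        support = sp.bootstrap_support(aq, refdb, n_reps=100, seed=5)
        assert support == pytest.approx(0.5, abs=0.15)


class TestEdgeDistance:
    def test_same_edge_zero(self, small_ref):
        refdb, _ = small_ref
        leaf = refdb.leaf_ids[0]
        assert edge_path_distance(refdb, leaf, leaf) == 0

    def test_sibling_edges_adjacent(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        aln = {k: "ACGTACGTACGT" * 10 for k in "ABCD"}
        refdb = sp.ReferenceDB(alignment=aln, tree=tree)
        assert edge_path_distance(refdb, "A", "B") == 1
        assert edge_path_distance(refdb, "A", "C") == 3
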