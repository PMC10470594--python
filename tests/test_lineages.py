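import random

import numpy as np
import pytest

import scoperon as sp
from scoperon.seqio import OperonRecord, Source
from scoperon.lineage_analysis import _AlignmentCache


@pytest.fixture(scope="module")
def cell_world():
    params = sp.SimParams(seed=2)
    refdb, truth = sp.simulate_reference(params)
    cells, truth = sp.simulate_cells(refdb, params, truth)
    cache = _AlignmentCache(refdb)
    return params, refdb, truth, cells, cache


class TestExcludeOfftarget:
    def test_planted_offtargets_removed_with_clade(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, excluded = sp.exclude_offtarget(
            cells, refdb, [truth.offtarget_clade], cache
        )
        assert {r.id for r, _ in excluded} == truth.offtarget_ids
        assert all(clade == truth.offtarget_clade for _, clade in excluded)
        assert len(kept) == len(cells) - len(truth.offtarget_ids)

    def test_no_excluded_clades_keeps_everything(self, cell_world):
        _, refdb, _, cells, cache = cell_world
        kept, excluded = sp.exclude_offtarget(cells, refdb, [], cache)
        assert kept == cells and excluded == []

    def test_unknown_clade_rejected(self, cell_world):
        _, refdb, _, cells, cache = cell_world
        with pytest.raises(ValueError, match="unknown clade"):
            sp.exclude_offtarget(cells, refdb, ["Shangri-La"], cache)


class TestClusterLineages:
    def test_identical_sequences_merge_across_cells(self, small_ref):
        refdb, _ = small_ref
        seq = refdb.alignment[refdb.leaf_ids[0]].replace("-", "")
        recs = [
            OperonRecord(id="c1.1", sample_id="c1", sequence=seq),
            OperonRecord(id="c2.1", sample_id="c2", sequence=seq),
        ]
        lineages = sp.cluster_lineages(recs, refdb)
        assert len(lineages) == 1
        assert lineages[0].member_cell_ids == {"c1", "c2"}

    def test_divergent_sequences_stay_apart(self, small_ref):
        refdb, _ = small_ref
        a = refdb.alignment[refdb.leaf_ids[0]].replace("-", "")
        rng = np.random.default_rng(0)
        b = list(a)
        for i in rng.choice(len(b), size=len(b) // 10, replace=False):  # 90% identity
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        recs = [
            OperonRecord(id="x", sequence=a),
            OperonRecord(id="y", sequence="".join(b)),
        ]
        assert len(sp.cluster_lineages(recs, refdb)) == 2

    def test_planted_lineages_recovered_exactly(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        lineages = sp.cluster_lineages(kept, refdb, cache=cache)
        assert len(lineages) == params.n_lineages
        planted = {}
        for rid, lid in truth.record_lineage.items():
            planted.setdefault(lid, set()).add(rid)
        assert sorted(
            [frozenset(l.member_record_ids) for l in lineages], key=sorted
        ) == sorted([frozenset(v) for v in planted.values()], key=sorted)

    def test_order_invariance_up_to_relabeling(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        subset = kept[:20]
        base = sp.cluster_lineages(subset, refdb, cache=cache)
        shuffled = subset[:]
        random.Random(3).shuffle(shuffled)
        other = sp.cluster_lineages(shuffled, refdb, cache=cache)
        part_a = sorted([frozenset(l.member_record_ids) for l in base], key=sorted)
        part_b = sorted([frozenset(l.member_record_ids) for l in other], key=sorted)
        assert part_a == part_b

    def test_threshold_monotonicity(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        subset = cells[:25]
        counts = [
            len(sp.cluster_lineages(subset, refdb, identity_threshold=t, cache=cache))
            for t in (0.90, 0.99, 0.999)
        ]
        assert counts == sorted(counts)

    def test_partition_property(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        lineages = sp.cluster_lineages(cells, refdb, cache=cache)
        seen = [rid for l in lineages for rid in l.member_record_ids]
        assert sorted(seen) == sorted(r.id for r in cells)


class TestMultiLineageCells:
    def test_planted_two_lineage_cells_found(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        lineages = sp.cluster_lineages(kept, refdb, cache=cache)
        multi = sp.detect_multi_lineage_cells(lineages)
        truth_multi = {c for c, ls in truth.cell_lineage_map.items() if len(ls) >= 2}
        assert set(multi) == truth_multi

    def test_two_records_one_lineage_not_reported(self, small_ref):
        refdb, _ = small_ref
        seq = refdb.alignment[refdb.leaf_ids[1]].replace("-", "")
        recs = [
            OperonRecord(id="c1.1", sample_id="c1", sequence=seq),
            OperonRecord(id="c1.2", sample_id="c1", sequence=seq),
        ]
        lineages = sp.cluster_lineages(recs, refdb)
        assert sp.detect_multi_lineage_cells(lineages) == {}


class TestAssignTaxonomy:
    def test_leaf_identical_representative_gets_full_path(self, small_ref):
        refdb, _ = small_ref
        leaf = refdb.leaf_ids[0]
        rec = OperonRecord(id="rep", sequence=refdb.alignment[leaf].replace("-", ""))
        (lineage,) = sp.cluster_lineages([rec], refdb)
        sp.assign_taxonomy(lineage, refdb)
        assert lineage.assigned_clade == refdb.taxonomy_for(leaf).rank_path
        assert lineage.novelty_rank is None

    def test_stem_edge_placement_is_novel_at_child_rank(self, cell_world):
        # a lineage placed on an internal edge is assigned the deepest
        # clade shared by the leaves above the edge, and novel one rank in
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        lineages = sp.cluster_lineages(kept, refdb, cache=cache)
        ranks = ("phylum", "order", "family", "genus", "species")
        for lin in lineages:
            sp.assign_taxonomy(lin, refdb)
            if lin.novelty_rank is None:
                continue
            assigned = [r for r, _ in lin.assigned_clade]
            assert lin.novelty_rank in ranks
            assert ranks.index(lin.novelty_rank) == len(assigned)


class TestEcologyFlags:
    def test_hyperparasite_flags_equal_truth(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        lineages = sp.cluster_lineages(kept, refdb, cache=cache)
        meta = {r.id: r.metadata for r in cells}
        flagged: set[str] = set()
        for lin in lineages:
            sp.assign_taxonomy(lin, refdb)
            if "putative_hyperparasite" in sp.flag_ecology_conflict(lin, meta, refdb):
                flagged |= lin.member_record_ids
        assert flagged == truth.hyperparasite_ids

    def test_missing_metadata_warns_and_yields_none(self, small_ref):
        refdb, _ = small_ref
        leaf = refdb.leaf_ids[0]
        rec = OperonRecord(id="rep", sequence=refdb.alignment[leaf].replace("-", ""))
        (lineage,) = sp.cluster_lineages([rec], refdb)
        with pytest.warns(UserWarning, match="no member metadata"):
            flags = sp.flag_ecology_conflict(lineage, {}, refdb)
        assert flags == {"none"}


class TestConcordance:
    def test_identical_otu_is_species_level(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        kept, _ = sp.exclude_offtarget(cells, refdb, [truth.offtarget_clade], cache)
        lineages = sp.cluster_lineages(kept[:6], refdb, cache=cache)
        rep_id = lineages[0].representative_id
        rep = next(r for r in kept if r.id == rep_id)
        otu = OperonRecord(id="OTUx", sequence=rep.sequence, source=Source.OTU)
        rows = sp.concordance(lineages, [otu], refdb, cache=cache)
        first = next(r for r in rows if r.lineage_id == lineages[0].lineage_id)
        assert first.match_level == "species_level"
        assert first.identity == pytest.approx(1.0)

    def test_no_otus_everything_unmatched(self, cell_world):
        params, refdb, truth, cells, cache = cell_world
        lineages = sp.cluster_lineages(cells[:4], refdb, cache=cache)
        rows = sp.concordance(lineages, [], refdb, cache=cache)
        assert all(r.match_level == "unmatched" for r in rows)
        assert all(r.nearest_otu_id is None for r in rows)
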