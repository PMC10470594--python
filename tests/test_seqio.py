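import warnings

import dendropy
import pytest
from hypothesis import given, settings, strategies as st

import scoperon as sp
from scoperon.seqio import (
    OperonRecord,
    Region,
    RegionAnnotation,
    Source,
    read_annotations,
    read_fasta,
    read_newick,
    write_fasta,
    write_newick,
)


class TestFasta:
    def test_case_and_rna_normalisation(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(">q1 extra tokens ignored\nacgu\n")
        (rec,) = read_fasta(p, Source.OTU)
        assert rec.id == "q1"
        assert rec.sequence == "ACGT"

    def test_duplicate_id_error_names_offender(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_wrapped_lines_match_line_reference_parser(self, tmp_path):
        # oracle: naive line-by-line concatenation
        seq1 = "ACGT" * 25  # 100 bp written as 70 + 30
        seq2 = "GGGTTTACCA"
        p = tmp_path / "wrap.fasta"
        p.write_text(f">one\n{seq1[:70]}\n{seq1[70:]}\n>two\n{seq2}\n")
        expected = {}
        name = None
        for line in p.read_text().splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                expected[name] = ""
            else:
                expected[name] += line.strip()
        records = read_fasta(p)
        assert {r.id: r.sequence for r in records} == expected
        assert [len(r.sequence) for r in records] == [100, 10]

    def test_non_iupac_character_reports_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACQT\n")
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.warns(UserWarning, match="no FASTA entries"):
            assert read_fasta(p) == []

    def test_gaps_stripped_from_raw_queries_but_kept_in_reference(self, tmp_path):
        p = tmp_path / "gap.fasta"
        p.write_text(">x\nAC-GT\n")
        with pytest.warns(UserWarning, match="stripping"):
            (rec,) = read_fasta(p, Source.OTU)
        assert rec.sequence == "ACGT"
        (ref,) = read_fasta(p, Source.REFERENCE)
        assert ref.sequence == "AC-GT"

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=1, max_size=120),
            min_size=1,
            max_size=5,
        )
    )
    def test_roundtrip_identity(self, tmp_path_factory, seqs):
        records = [
            OperonRecord(id=f"r{i}", sequence=s, source=Source.OTU)
            for i, s in enumerate(seqs)
        ]
        path = tmp_path_factory.mktemp("fa") / "round.fasta"
        write_fasta(records, path)
        back = read_fasta(path, Source.OTU)
        assert {r.id: r.sequence for r in back} == {
            r.id: r.sequence for r in records
        }


class TestRecordInvariants:
    def test_region_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            OperonRecord(
                id="x",
                sequence="ACGT",
                regions=[RegionAnnotation(Region.SSU18S, 0, 10)],
            )

    def test_overlapping_regions_rejected(self):
        regs = [
            RegionAnnotation(Region.SSU18S, 0, 5),
            RegionAnnotation(Region.ITS1, 3, 8),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            OperonRecord(id="x", sequence="ACGTACGTAC", regions=regs)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_valid_partitions_always_accepted(self, data):
        n = data.draw(st.integers(min_value=10, max_value=60))
        seq = "A" * n
        cut1 = data.draw(st.integers(min_value=1, max_value=n - 2))
        cut2 = data.draw(st.integers(min_value=cut1 + 1, max_value=n - 1))
        rec = OperonRecord(
            id="x",
            sequence=seq,
            regions=[
                RegionAnnotation(Region.SSU18S, 0, cut1),
                RegionAnnotation(Region.ITS1, cut1, cut2),
                RegionAnnotation(Region.R5_8S, cut2, n),
            ],
        )
        assert all(a.end <= len(rec.sequence) for a in rec.regions)


class TestNewick:
    def test_total_branch_length_and_leaves(self, tmp_path):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert len(t.leaf_nodes()) == 3
        total = sum(e.length for e in t.preorder_edge_iter() if e.length)
        assert total == pytest.approx(5.0)

    def test_missing_lengths_default_zero(self):
        t = read_newick("(A,B);")
        assert all(e.length == 0.0 for e in t.preorder_edge_iter())

    def test_unbalanced_parentheses_reports_offset(self):
        with pytest.raises(ValueError, match="offset"):
            read_newick("((A:1,B:1):1,C:2;")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate leaf"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_random_tree_roundtrip(self):
        import random
        from dendropy.simulate import treesim

        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=20, rng=random.Random(4)
        )
        text = write_newick(tree)
        back = read_newick(text)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=text, schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(
            data=write_newick(back), schema="newick", taxon_namespace=tns
        )
        a.encode_bipartitions()
        b.encode_bipartitions()
        from dendropy.calculate import treecompare

        assert treecompare.symmetric_difference(a, b) == 0
        la = {lf.taxon.label: lf.edge.length for lf in a.leaf_node_iter()}
        lb = {lf.taxon.label: lf.edge.length for lf in b.leaf_node_iter()}
        assert la == pytest.approx(lb)


class TestAnnotations:
    def test_metadata_row(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "sample_id\thost_taxon\thabit\nPSC289\tMougeotia\tepibiotic\n"
        )
        meta, taxo = read_annotations(p)
        assert taxo == []
        assert meta["PSC289"]["habit"] == "epibiotic"
        assert meta["PSC289"]["host_taxon"] == "Mougeotia"

    def test_column_order_irrelevant(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("sample_id\thost_taxon\thabit\nX\tSpirogyra\tendobiotic\n")
        b.write_text("habit\tsample_id\thost_taxon\nendobiotic\tX\tSpirogyra\n")
        assert read_annotations(a) == read_annotations(b)

    def test_unknown_enum_maps_to_unknown_with_warning(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\thost_taxon\thabit\nX\tY\tfloating\n")
        with pytest.warns(UserWarning, match="unknown habit"):
            meta, _ = read_annotations(p)
        assert meta["X"]["habit"] == "unknown"

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\thost_taxon\nX\tY\n")
        with pytest.raises(ValueError, match="habit"):
            read_annotations(p)

    def test_empty_metadata_file(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\thost_taxon\thabit\n")
        meta, taxo = read_annotations(p)
        assert meta == {} and taxo == []

    def test_taxonomy_dialect(self, tmp_path):
        p = tmp_path / "taxo.tsv"
        p.write_text(
            "leaf_id\tphylum\tfamily\tspecies\ttrophic_mode\n"
            "R1\tphyA\tfamB\tR1\tparasite_of_algae\n"
        )
        _, taxo = read_annotations(p)
        assert taxo[0].name_at("family") == "famB"
        assert taxo[0].trophic_mode == "parasite_of_algae"
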