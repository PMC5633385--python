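import random

import pytest

from clusterkin import formats_io as fio
from clusterkin.formats_io import ParseError


def _write(tmp_path, name, content):
    p = tmp_path / name
    p.write_text(content)
    return p


class TestSequenceIds:
    def test_single_line(self, tmp_path):
        p = _write(tmp_path, "s.txt", "0_0: A_prot1\n")
        sm = fio.parse_sequence_ids(p, ["A", "B"])
        assert sm.entries == {"0_0": ("A_prot1", "A")}

    def test_counts_match_file(self, bundle):
        n_lines = sum(
            1 for ln in (bundle.directory / "SequenceIDs.txt")
            .read_text().splitlines() if ln.strip())
        assert len(bundle.seqmap) == n_lines
        assert set(bundle.seqmap.proteome_ids) == set(bundle.attrs.proteomes)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "s.txt", "0_0 A_prot1\n")
        with pytest.raises(ParseError) as exc:
            fio.parse_sequence_ids(p, ["A"])
        assert exc.value.line == 1

    def test_duplicate_token_rejected(self, tmp_path):
        p = _write(tmp_path, "s.txt", "0_0: x\n0_0: y\n")
        with pytest.raises(ParseError, match="duplicate token"):
            fio.parse_sequence_ids(p, ["A"])


class TestClustering:
    def test_two_member_cluster(self, tmp_path):
        seqmap = fio.SequenceMap({"0_0": ("a1", "A"), "1_0": ("b1", "B")})
        p = _write(tmp_path, "c.txt", "OG0: 0_0 1_0\n")
        cc = fio.parse_clustering(p, seqmap)
        assert len(cc) == 1
        assert cc["OG0"].size == 2
        assert cc["OG0"].proteome_count == 2

    def test_raw_protein_ids_autodetected(self, tmp_path):
        seqmap = fio.SequenceMap({"0_0": ("a1", "A"), "1_0": ("b1", "B")})
        p = _write(tmp_path, "c.txt", "OG0: a1 b1\n")
        cc = fio.parse_clustering(p, seqmap)
        assert cc["OG0"].members == {"A": ("a1",), "B": ("b1",)}

    def test_member_total_matches_token_count(self, bundle):
        text = (bundle.directory / "Orthogroups.txt").read_text()
        n_tokens = sum(len(ln.split(":")[1].split())
                       for ln in text.splitlines() if ln.strip())
        assert bundle.clusters.total_proteins == n_tokens

    def test_unknown_token_rejected(self, tmp_path):
        seqmap = fio.SequenceMap({"0_0": ("a1", "A")})
        p = _write(tmp_path, "c.txt", "OG0: 0_0 9_9\n")
        with pytest.raises(ParseError, match="9_9"):
            fio.parse_clustering(p, seqmap)

    def test_protein_in_two_clusters_rejected(self, tmp_path):
        seqmap = fio.SequenceMap({"0_0": ("a1", "A"), "0_1": ("a2", "A")})
        p = _write(tmp_path, "c.txt", "OG0: 0_0\nOG1: 0_0 0_1\n")
        with pytest.raises(ParseError, match="two clusters"):
            fio.parse_clustering(p, seqmap)

    def test_infer_singletons_adds_unclustered(self, tmp_path):
        seqmap = fio.SequenceMap({"0_0": ("a1", "A"), "0_1": ("a2", "A")})
        p = _write(tmp_path, "c.txt", "OG0: 0_0\n")
        cc = fio.parse_clustering(p, seqmap, infer_singletons=True)
        assert len(cc) == 2
        assert cc["singleton_0"].members == {"A": ("a2",)}

    def test_round_trip(self, bundle, tmp_path):
        out = tmp_path / "rt.txt"
        fio.write_clustering(bundle.clusters, out)
        again = fio.parse_clustering(out, bundle.seqmap)
        assert [(c.cluster_id, c.members) for c in bundle.clusters] == \
               [(c.cluster_id, c.members) for c in again]

    def test_line_permutation_changes_nothing_but_order(self, bundle,
                                                        tmp_path):
        lines = (bundle.directory / "Orthogroups.txt").read_text() \
            .splitlines()
        random.Random(0).shuffle(lines)
        p = _write(tmp_path, "shuffled.txt", "\n".join(lines) + "\n")
        shuffled = fio.parse_clustering(p, bundle.seqmap)
        assert {c.cluster_id: c.members for c in shuffled} == \
               {c.cluster_id: c.members for c in bundle.clusters}


class TestConfig:
    def test_levels_and_injected_attributes(self, tmp_path):
        p = _write(tmp_path, "c.csv",
                   "#IDX,TAXON,host\n0,A,human\n1,B,human\n2,C,other\n")
        at = fio.parse_config(p)
        assert at.levels("host") == {"human": {"A", "B"}, "other": {"C"}}
        assert at.levels("all") == {"all": {"A", "B", "C"}}
        assert at.levels("TAXON") == {"A": {"A"}, "B": {"B"}, "C": {"C"}}

    def test_duplicate_proteome_rejected(self, tmp_path):
        p = _write(tmp_path, "c.csv", "#IDX,TAXON,h\n0,A,x\n1,A,y\n")
        with pytest.raises(ParseError, match="duplicate proteome"):
            fio.parse_config(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "c.csv", "#IDX,TAXON,h\n0,A,\n")
        with pytest.raises(ParseError, match="missing level"):
            fio.parse_config(p)

    def test_taxid_column_collected(self, tmp_path):
        p = _write(tmp_path, "c.csv",
                   "#IDX,TAXON,TAXID\n0,A,10\n1,B,20\n")
        at = fio.parse_config(p)
        assert at.taxid_of == {"A": "10", "B": "20"}
        assert at.attributes == ["TAXON", "all"]


IPS_ROW = ("p1\tmd5\t300\tPfam\tPF00001\tkinase\t1\t60\t1e-10\tT\t"
           "01-01-2020\tIPR000001\tkinase entry\t"
           "GO:0005524|GO:0016021")


class TestFunctionalAnnotation:
    def test_one_row_yields_four_records(self, tmp_path):
        p = _write(tmp_path, "a.tsv", IPS_ROW + "\n")
        at = fio.parse_functional_annotation(p)
        terms = at.terms_of("p1")
        assert len(terms) == 4
        assert {src for src, _, _ in terms} == {"Pfam", "IPR", "GO"}
        assert sum(1 for src, _, _ in terms if src == "GO") == 2

    def test_repeated_domain_hits_collapse(self, tmp_path):
        p = _write(tmp_path, "a.tsv", IPS_ROW + "\n" + IPS_ROW + "\n")
        at = fio.parse_functional_annotation(p)
        assert len(at.terms_of("p1", "Pfam")) == 1

    def test_distinct_protein_count(self, bundle):
        accessions = {ln.split("\t")[0]
                      for ln in (bundle.directory / "interproscan.tsv")
                      .read_text().splitlines() if ln.strip()}
        assert bundle.annotations.proteins == accessions

    def test_wrong_column_count_rejected(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "p1\tonly\tthree\n")
        with pytest.raises(ParseError) as exc:
            fio.parse_functional_annotation(p)
        assert exc.value.line == 1


class TestFastaLengths:
    def test_length_and_stop_strip(self, tmp_path):
        p1 = _write(tmp_path, "a.fa", ">p1 desc\nMKV\n")
        p2 = _write(tmp_path, "b.fa", ">p2\nMKV*\n")
        lt = fio.read_fasta_lengths([p1, p2])
        assert lt["p1"] == 3
        assert lt["p2"] == 3

    def test_duplicate_id_across_files_rejected(self, tmp_path):
        p1 = _write(tmp_path, "a.fa", ">p1\nMKV\n")
        p2 = _write(tmp_path, "b.fa", ">p1\nMM\n")
        with pytest.raises(ParseError, match="duplicate"):
            fio.read_fasta_lengths([p1, p2])

    def test_generated_lengths_match_manifest(self, bundle):
        assert all(bundle.lengths[k] == v
                   for k, v in bundle.manifest["lengths"].items())


class TestTree:
    def test_outgroup_rooting(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,B),C);\n")
        tree = fio.parse_tree(p, ["C"])
        root_kids = {frozenset(tree.leaves_under[c])
                     for c in tree.children[tree.root]}
        assert root_kids == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_root_covers_all_leaves(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,B),(C,D));\n")
        tree = fio.parse_tree(p, ["C", "D"])
        assert tree.leaves_under[tree.root] == {"A", "B", "C", "D"}

    def test_preorder_internal_labels(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,(B,C)),D);\n")
        tree = fio.parse_tree(p, ["D"])
        by_label = {n: tree.leaves_under[n] for n in tree.internal_nodes}
        assert by_label["n0"] == {"A", "B", "C", "D"}
        assert by_label["n1"] == {"A", "B", "C"}
        assert by_label["n2"] == {"B", "C"}

    def test_unknown_outgroup_rejected(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,B),C);\n")
        with pytest.raises(ParseError, match="outgroup"):
            fio.parse_tree(p, ["Z"])

    def test_leaf_missing_from_config_rejected(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,B),C);\n")
        attrs = fio.AttributeTable(["A", "B"], [], {})
        with pytest.raises(ParseError, match="not in config"):
            fio.parse_tree(p, ["B"], attrs)

    def test_mrca(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,(B,C)),D);\n")
        tree = fio.parse_tree(p, ["D"])
        assert tree.mrca({"B", "C"}) == "n2"
        assert tree.mrca({"A", "C"}) == "n1"
        assert tree.mrca({"A", "D"}) == "n0"


class TestTaxonomyRanks:
    def test_rank_expansion(self, bundle):
        at = fio.expand_taxonomy_ranks(
            bundle.attrs, bundle.directory / "taxdump",
            ["phylum", "order", "genus"])
        assert at.levels("phylum") == {
            "Synthophyla": set(bundle.attrs.proteomes)}
        # consecutive proteomes share a genus by construction
        genus = at.levels("genus")
        assert {"PRO0", "PRO1"} in genus.values()

    def test_missing_rank_is_undef(self, tmp_path):
        tax = tmp_path / "taxdump"
        tax.mkdir()
        (tax / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\tspecies\t|\n")
        (tax / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tSp x\t|\t\t|\tscientific name\t|\n")
        attrs = fio.AttributeTable(["A"], [], {}, {"A": "2"})
        out = fio.expand_taxonomy_ranks(attrs, tax, ["genus"])
        assert out.levels("genus") == {"undef": {"A"}}

    def test_unknown_taxid_warns_and_undef(self, tmp_path):
        tax = tmp_path / "taxdump"
        tax.mkdir()
        (tax / "nodes.dmp").write_text("1\t|\t1\t|\tno rank\t|\n")
        (tax / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n")
        attrs = fio.AttributeTable(["A"], [], {}, {"A": "99"})
        with pytest.warns(UserWarning, match="absent from taxdump"):
            out = fio.expand_taxonomy_ranks(attrs, tax, ["phylum"])
        assert out.levels("phylum") == {"undef": {"A"}}
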