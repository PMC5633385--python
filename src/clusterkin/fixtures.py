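"""Deterministic synthetic input bundles with known ground truth.

Real inputs for this kind of analysis are the products of a long
upstream pipeline (proteome prediction, all-vs-all similarity search,
MCL clustering, domain annotation), so the generator here fabricates a
complete, internally consistent bundle in exactly the dialects the
readers expect — orthogroup file, SequenceIDs, config table,
InterProScan TSV, proteome FASTAs, Newick topology, and a miniature
NCBI-style taxdump — together with a manifest of the ground truth that
was planted: cluster types, single-copy orthologs, synapomorphy
placements, representative annotations, and sequence lengths.

The generator plants structure; it does not simulate protein evolution
or re-run orthology inference. Sequences are random residue strings of
the specified lengths.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from clusterkin.formats_io import (
    AnnotationTable,
    AttributeTable,
    Cluster,
    ClusterCollection,
    LengthTable,
    SequenceMap,
    TreeTopology,
    parse_clustering,
    parse_config,
    parse_functional_annotation,
    parse_sequence_ids,
    parse_tree,
    read_fasta_lengths,
)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Bundle:
    """In-memory view of a generated (or embedded) input bundle."""

    clusters: ClusterCollection
    attrs: AttributeTable
    seqmap: SequenceMap
    tree: TreeTopology | None
    lengths: LengthTable | None
    annotations: AnnotationTable | None
    manifest: dict
    directory: Path | None = None


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic bundle.

    ``synapomorphies_per_node`` may be a single count applied to every
    internal node or a mapping from node index to count; node 0 is the
    root and node i (i >= 1) is the ladder node spanning the first
    ``n_proteomes - i`` proteomes.
    """

    n_proteomes: int = 6
    synapomorphies_per_node: int | Mapping[int, int] = 2
    partial_absence_per_node: int = 0
    n_singletons_per_proteome: int = 2
    n_true_scos: int = 4
    n_fuzzy_scos: int = 3
    fuzzy_target_count: int = 1
    fuzzy_min: int = 1
    fuzzy_max: int = 2
    annotation_coverage: float = 0.5
    secreted_coverage: float = 0.25
    length_mean: float = 350.0
    length_sd: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteomes < 3:
            raise ValueError("need at least 3 proteomes")
        for name in ("synapomorphies", "partial_absence"):
            pass
        if isinstance(self.synapomorphies_per_node, Mapping):
            bad = [k for k in self.synapomorphies_per_node
                   if not (0 <= k <= self.n_proteomes - 2)]
            if bad:
                raise ValueError(
                    f"synapomorphy counts reference nonexistent node "
                    f"index(es) {bad}; valid range is 0.."
                    f"{self.n_proteomes - 2}")
        for frac in (self.annotation_coverage, self.secreted_coverage):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("coverage fractions must be in [0, 1]")
        if not (0 <= self.fuzzy_min <= self.fuzzy_target_count
                <= self.fuzzy_max):
            raise ValueError("need 0 <= fuzzy_min <= fuzzy_target_count "
                             "<= fuzzy_max")


def _ladder_nodes(proteomes: list[str]) -> list[list[str]]:
    """Leaf sets of the ladder tree's internal nodes, root first.

    Node 0 is the root (all proteomes); node i spans the first
    ``n - i`` proteomes.
    """
    n = len(proteomes)
    return [proteomes[: n - i] for i in range(n - 1)]


def _ladder_newick(proteomes: list[str]) -> str:
    nwk = f"({proteomes[0]},{proteomes[1]})"
    for p in proteomes[2:]:
        nwk = f"({nwk},{p})"
    return nwk + ";"


def generate_bundle(spec: FixtureSpec, outdir: str | Path) -> Bundle:
    """Write a complete synthetic input bundle and its manifest.

    Byte-identical for a given spec (including its seed). The bundle
    is immediately re-read through the format readers, so what is
    returned is exactly what an analysis run would see.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    n = spec.n_proteomes
    proteomes = [f"PRO{i}" for i in range(n)]
    node_leafsets = _ladder_nodes(proteomes)

    # --- plan clusters -----------------------------------------------------
    # each planned cluster: (cid, {proteome: n_copies}, intended_node_index)
    planned: list[tuple[str, dict[str, int], int | None]] = []
    cid_counter = 0

    def next_cid() -> str:
        nonlocal cid_counter
        cid = f"OG{cid_counter:07d}"
        cid_counter += 1
        return cid

    syn_counts: dict[int, int]
    if isinstance(spec.synapomorphies_per_node, Mapping):
        syn_counts = dict(spec.synapomorphies_per_node)
    else:
        syn_counts = {i: spec.synapomorphies_per_node
                      for i in range(len(node_leafsets))}
    for node_idx, leafset in enumerate(node_leafsets):
        for _ in range(syn_counts.get(node_idx, 0)):
            planned.append((next_cid(), {p: 1 for p in leafset}, node_idx))
        if len(leafset) >= 3:  # cherry nodes cannot lose a leaf and
            #                    keep both children supported
            for _ in range(spec.partial_absence_per_node):
                # drop one leaf from the larger (ladder) child; the
                # terminal leaf of the node stays, so both children
                # keep support
                dropped = leafset[0]
                members = {p: 1 for p in leafset if p != dropped}
                planned.append((next_cid(), members, node_idx))
    for _ in range(spec.n_true_scos):
        planned.append((next_cid(), {p: 1 for p in proteomes}, 0))
    fuzzy: list[str] = []
    for _ in range(spec.n_fuzzy_scos):
        cid = next_cid()
        counts = {p: spec.fuzzy_target_count for p in proteomes}
        # push one proteome off target but inside [min, max]
        off = rng.choice(proteomes)
        alternatives = [c for c in range(spec.fuzzy_min, spec.fuzzy_max + 1)
                        if c != spec.fuzzy_target_count]
        if alternatives:
            counts[off] = rng.choice(alternatives)
        counts = {p: c for p, c in counts.items() if c > 0}
        planned.append((cid, counts, 0 if len(counts) > 1 else None))
        fuzzy.append(cid)
    singletons: dict[str, list[str]] = {p: [] for p in proteomes}
    for p in proteomes:
        for _ in range(spec.n_singletons_per_proteome):
            cid = next_cid()
            planned.append((cid, {p: 1}, None))
            singletons[p].append(cid)
    # strict SCOs are a property of copy counts, not of intent: root
    # synapomorphies planted with one copy per proteome qualify too
    true_scos = [cid for cid, counts, _ in planned
                 if len(counts) == n and all(c == 1 for c in counts.values())]

    # --- materialise proteins ---------------------------------------------
    per_proteome_proteins: dict[str, list[str]] = {p: [] for p in proteomes}
    cluster_members: dict[str, dict[str, list[str]]] = {}
    for cid, counts, _ in planned:
        members: dict[str, list[str]] = {}
        for p, c in counts.items():
            for _ in range(c):
                prot = f"{p}.p{len(per_proteome_proteins[p]):04d}"
                per_proteome_proteins[p].append(prot)
                members.setdefault(p, []).append(prot)
        cluster_members[cid] = members

    lengths: dict[str, int] = {}
    for p in proteomes:
        for prot in per_proteome_proteins[p]:
            lengths[prot] = max(30, int(rng.gauss(spec.length_mean,
                                                  spec.length_sd)))

    # --- choose annotated / secreted clusters -----------------------------
    nonsingleton_cids = [cid for cid, counts, _ in planned
                         if sum(counts.values()) > 1]
    n_annot = round(spec.annotation_coverage * len(nonsingleton_cids))
    n_secr = round(spec.secreted_coverage * len(nonsingleton_cids))
    annotated_cids = nonsingleton_cids[:n_annot]
    secreted_cids = nonsingleton_cids[:n_secr]
    annotated_terms: dict[str, dict[str, str]] = {}
    for k, cid in enumerate(annotated_cids):
        annotated_terms[cid] = {
            "Pfam": f"PF{10000 + k:05d}",
            "IPR": f"IPR{100000 + k:06d}",
            "GO": f"GO:{7000000 + k:07d}",
        }

    # --- write files -------------------------------------------------------
    with (outdir / "SequenceIDs.txt").open("w") as fh:
        for i, p in enumerate(proteomes):
            for j, prot in enumerate(per_proteome_proteins[p]):
                fh.write(f"{i}_{j}: {prot}\n")
    token_of = {prot: f"{i}_{j}"
                for i, p in enumerate(proteomes)
                for j, prot in enumerate(per_proteome_proteins[p])}
    with (outdir / "Orthogroups.txt").open("w") as fh:
        for cid, counts, _ in planned:
            toks = [token_of[prot]
                    for p in sorted(counts)
                    for prot in cluster_members[cid][p]]
            fh.write(f"{cid}: {' '.join(toks)}\n")
    with (outdir / "config.csv").open("w") as fh:
        fh.write("#IDX,TAXON,habitat,TAXID\n")
        for i, p in enumerate(proteomes):
            habitat = "host" if i < n // 2 else "free"
            fh.write(f"{i},{p},{habitat},{2000 + i}\n")
    with (outdir / "tree.nwk").open("w") as fh:
        fh.write(_ladder_newick(proteomes) + "\n")

    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(exist_ok=True)
    for p in proteomes:
        with (fasta_dir / f"{p}.faa").open("w") as fh:
            for prot in per_proteome_proteins[p]:
                seq = "".join(rng.choice(_RESIDUES)
                              for _ in range(lengths[prot]))
                fh.write(f">{prot}\n{seq}\n")

    with (outdir / "interproscan.tsv").open("w") as fh:
        for cid in nonsingleton_cids:
            for p in sorted(cluster_members[cid]):
                for prot in cluster_members[cid][p]:
                    L = lengths[prot]
                    if cid in annotated_terms:
                        t = annotated_terms[cid]
                        fh.write("\t".join([
                            prot, "0" * 32, str(L), "Pfam", t["Pfam"],
                            f"synthetic domain {t['Pfam']}", "1",
                            str(min(L, 60)), "1.0E-10", "T", "01-01-2020",
                            t["IPR"], f"synthetic entry {t['IPR']}",
                            t["GO"]]) + "\n")
                    if cid in secreted_cids:
                        fh.write("\t".join([
                            prot, "0" * 32, str(L), "SignalP_Euk",
                            "SignalP-noTM", "", "1", "20", "0.9", "T",
                            "01-01-2020"]) + "\n")

    tax_dir = outdir / "taxdump"
    tax_dir.mkdir(exist_ok=True)
    # lineage: species (2000+i) -> genus (1000+i//2) -> order (100/101)
    #          -> phylum (10) -> root (1)
    nodes = [("1", "1", "no rank"), ("10", "1", "phylum"),
             ("100", "10", "order"), ("101", "10", "order")]
    names = [("1", "root"), ("10", "Synthophyla"),
             ("100", "Alphaorder"), ("101", "Betaorder")]
    for i, p in enumerate(proteomes):
        genus = 1000 + i // 2
        order = "100" if i < n // 2 else "101"
        if not any(t[0] == str(genus) for t in nodes):
            nodes.append((str(genus), order, "genus"))
            names.append((str(genus), f"Genusium{i // 2}"))
        nodes.append((str(2000 + i), str(genus), "species"))
        names.append((str(2000 + i), f"Genusium{i // 2} specius{i}"))
    with (tax_dir / "nodes.dmp").open("w") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with (tax_dir / "names.dmp").open("w") as fh:
        for taxid, name in names:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")

    # --- manifest ----------------------------------------------------------
    manifest = {
        "spec": {
            "n_proteomes": n,
            "seed": spec.seed,
            "fuzzy_params": {
                "target_count": spec.fuzzy_target_count,
                "min": spec.fuzzy_min,
                "max": spec.fuzzy_max,
            },
        },
        "proteomes": proteomes,
        "clusters": {cid: {p: cluster_members[cid][p]
                           for p in sorted(cluster_members[cid])}
                     for cid, _, _ in planned},
        "true_scos": true_scos,
        "fuzzy_scos": fuzzy,
        "singletons": singletons,
        "synapomorphies": {
            cid: {
                "leaves": sorted(counts),
                "node_leaves": sorted(node_leafsets[node_idx]),
                "coverage": len(counts) / len(node_leafsets[node_idx]),
            }
            for cid, counts, node_idx in planned
            if node_idx is not None and len(counts) > 1
        },
        "annotated": annotated_terms,
        "secreted": secreted_cids,
        "lengths": lengths,
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return load_bundle(outdir)


def load_bundle(directory: str | Path) -> Bundle:
    """Re-read a generated bundle through the standard format readers."""
    directory = Path(directory)
    attrs = parse_config(directory / "config.csv")
    seqmap = parse_sequence_ids(directory / "SequenceIDs.txt",
                                attrs.proteomes)
    clusters = parse_clustering(directory / "Orthogroups.txt", seqmap)
    tree = None
    tree_path = directory / "tree.nwk"
    if tree_path.exists():
        tree = parse_tree(tree_path, [attrs.proteomes[-1]], attrs)
    lengths = None
    fasta_dir = directory / "fasta"
    if fasta_dir.is_dir():
        lengths = read_fasta_lengths(sorted(fasta_dir.glob("*.faa")))
    annotations = None
    ipr_path = directory / "interproscan.tsv"
    if ipr_path.exists():
        annotations = parse_functional_annotation(ipr_path)
    manifest = {}
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    return Bundle(clusters, attrs, seqmap, tree, lengths, annotations,
                  manifest, directory)


# ---------------------------------------------------------------------------
# the embedded three-proteome worked example
# ---------------------------------------------------------------------------

#: proteomes and their proteins
_TOY3_PROTEINS = {
    "A": ["a1", "a2", "a3", "a4", "a5"],
    "B": ["b1", "b2", "b3", "b4"],
    "C": ["c1", "c2", "c3"],
}
#: cluster membership
_TOY3_CLUSTERS = {
    "OG0": {"A": ["a1"], "B": ["b1"], "C": ["c1"]},
    "OG1": {"A": ["a2"], "B": ["b2"]},
    "OG2": {"A": ["a3", "a4"]},
    "OG3": {"B": ["b3"]},
    "OG4": {"A": ["a5"], "B": ["b4"], "C": ["c2"]},
    "OG5": {"C": ["c3"]},
}
_TOY3_HOST = {"A": "human", "B": "human", "C": "other"}
_TOY3_LENGTHS = {
    "a1": 100, "a2": 200, "a3": 120, "a4": 130, "a5": 140,
    "b1": 105, "b2": 115, "b3": 125, "b4": 135,
    "c1": 95, "c2": 105, "c3": 115,
}
_TOY3_NEWICK = "((A,B),C);"


def toy3_fixture(outdir: str | Path | None = None) -> Bundle:
    """The three-proteome, six-cluster worked example.

    Proteome A contributes a1..a5, B b1..b4, C c1..c3. OG0 and OG4 are
    universal single-copy clusters, OG1 is shared by A and B, OG2 is an
    A-specific pair, OG3 and OG5 are singletons. The ``host`` attribute
    groups A and B as ``human`` against C as ``other``; the tree is
    ((A,B),C) rooted on C. OG0 is fully Pfam/IPR/GO-annotated and a2
    carries a signal peptide.

    With *outdir* the bundle is also written to disk in the standard
    file dialects (for CLI runs and round-trip checks).
    """
    proteomes = list(_TOY3_PROTEINS)
    files: dict[str, str] = {}
    seq_lines = []
    token_of: dict[str, str] = {}
    for i, p in enumerate(proteomes):
        for j, prot in enumerate(_TOY3_PROTEINS[p]):
            token_of[prot] = f"{i}_{j}"
            seq_lines.append(f"{i}_{j}: {prot}")
    files["SequenceIDs.txt"] = "\n".join(seq_lines) + "\n"
    files["Orthogroups.txt"] = "".join(
        f"{cid}: " + " ".join(token_of[prot]
                              for p in members for prot in members[p])
        + "\n"
        for cid, members in _TOY3_CLUSTERS.items())
    files["config.csv"] = "#IDX,TAXON,host\n" + "".join(
        f"{i},{p},{_TOY3_HOST[p]}\n" for i, p in enumerate(proteomes))
    files["tree.nwk"] = _TOY3_NEWICK + "\n"
    ipr_rows = []
    for prot in ("a1", "b1", "c1"):
        L = _TOY3_LENGTHS[prot]
        ipr_rows.append("\t".join([
            prot, "0" * 32, str(L), "Pfam", "PF00001", "toy domain", "1",
            "60", "1.0E-10", "T", "01-01-2020", "IPR000001", "toy entry",
            "GO:0005524"]))
    ipr_rows.append("\t".join([
        "a2", "0" * 32, str(_TOY3_LENGTHS["a2"]), "SignalP_Euk",
        "SignalP-noTM", "", "1", "20", "0.9", "T", "01-01-2020"]))
    files["interproscan.tsv"] = "\n".join(ipr_rows) + "\n"

    manifest = {
        "proteomes": proteomes,
        "clusters": _TOY3_CLUSTERS,
        "n_clusters": 6,
        "singletons": ["OG3", "OG5"],
        "proteome_specific_nonsingleton": ["OG2"],
        "true_scos": ["OG0", "OG4"],
        "cooccurrence_AB": 3,
        "cooccurrence_AB_excluding_universal": 1,
        "nonsingleton_clusters": ["OG0", "OG1", "OG2", "OG4"],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, content in files.items():
            (outdir / name).write_text(content)
        fasta_dir = outdir / "fasta"
        fasta_dir.mkdir(exist_ok=True)
        rng = random.Random(42)
        for p in proteomes:
            with (fasta_dir / f"{p}.faa").open("w") as fh:
                for prot in _TOY3_PROTEINS[p]:
                    seq = "".join(rng.choice(_RESIDUES)
                                  for _ in range(_TOY3_LENGTHS[prot]))
                    fh.write(f">{prot}\n{seq}\n")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))

    attrs = AttributeTable(proteomes, ["host"],
                           {(p, "host"): _TOY3_HOST[p] for p in proteomes})
    seqmap = SequenceMap({token_of[prot]: (prot, p)
                          for p in proteomes
                          for prot in _TOY3_PROTEINS[p]})
    clusters = ClusterCollection(
        tuple(Cluster(cid, {p: tuple(v) for p, v in members.items()})
              for cid, members in _TOY3_CLUSTERS.items()),
        tuple(proteomes))
    # tree ((A,B),C) rooted on C: root n0 = {A,B} vs C, n1 = {A,B}
    tree = TreeTopology(
        root="n0",
        children={"n0": ("n1", "C"), "n1": ("A", "B")},
        leaves_under={"n0": frozenset({"A", "B", "C"}),
                      "n1": frozenset({"A", "B"}),
                      "A": frozenset({"A"}), "B": frozenset({"B"}),
                      "C": frozenset({"C"})})
    lengths = LengthTable(dict(_TOY3_LENGTHS))
    ann_records: dict[str, dict[tuple[str, str], str]] = {}
    for prot in ("a1", "b1", "c1"):
        ann_records[prot] = {
            ("Pfam", "PF00001"): "toy domain",
            ("IPR", "IPR000001"): "toy entry",
            ("GO", "GO:0005524"): "",
        }
    ann_records["a2"] = {("SignalP_Euk", "SignalP-noTM"): ""}
    annotations = AnnotationTable(ann_records)
    return Bundle(clusters, attrs, seqmap, tree, lengths, annotations,
                  manifest, Path(outdir) if outdir is not None else None)
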