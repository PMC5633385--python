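"""Readers and validators for every external file format.

All downstream analysis modules consume only the domain types built here:

* :class:`SequenceMap` — OrthoFinder ``SequenceIDs.txt`` (internal token
  ``<proteomeIdx>_<seqIdx>`` to protein ID and proteome ID)
* :class:`ClusterCollection` / :class:`Cluster` — orthogroup file
  (``<clusterID>: <member> <member> ...``)
* :class:`AttributeTable` — the config table mapping proteomes to levels
  of arbitrary attributes (plus the injected ``all`` and ``TAXON``
  attributes, and optional NCBI TaxIDs)
* :class:`AnnotationTable` — InterProScan TSV, collapsed to unique
  (protein, namespace, term) records
* :class:`LengthTable` — residue counts from proteome FASTA files
* :class:`TreeTopology` — rooted Newick topology with preorder-labelled
  internal nodes and precomputed descendant-leaf sets
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

RESERVED_ALL = "all"
RESERVED_TAXON = "TAXON"
#: InterProScan "analysis" values are passed through verbatim as namespaces;
#: these two are synthesized from the InterPro-accession and GO columns.
NAMESPACE_IPR = "IPR"
NAMESPACE_GO = "GO"
#: analysis value marking putatively secreted proteins (signal peptide).
NAMESPACE_SIGNALP = "SignalP_Euk"


class ParseError(ValueError):
    """Malformed input file; carries file path and 1-based line number."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceMap:
    """Maps internal sequence tokens ``<i>_<j>`` to (proteinID, proteomeID)."""

    entries: Mapping[str, tuple[str, str]]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    @property
    def proteome_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pid in self.entries.values():
            seen.setdefault(pid)
        return list(seen)

    def protein_of(self, token: str) -> str:
        return self.entries[token][0]

    def proteome_of(self, token: str) -> str:
        return self.entries[token][1]


@dataclass(frozen=True)
class Cluster:
    """One orthology cluster: per-proteome protein membership."""

    cluster_id: str
    members: Mapping[str, tuple[str, ...]]

    @property
    def size(self) -> int:
        """Total number of proteins in the cluster."""
        return sum(len(v) for v in self.members.values())

    @property
    def proteome_count(self) -> int:
        """Number of proteomes contributing at least one protein."""
        return sum(1 for v in self.members.values() if v)

    @property
    def proteomes(self) -> frozenset[str]:
        return frozenset(p for p, v in self.members.items() if v)

    @property
    def proteins(self) -> list[str]:
        out: list[str] = []
        for p in self.members.values():
            out.extend(p)
        return out

    def count(self, proteome_id: str) -> int:
        return len(self.members.get(proteome_id, ()))


@dataclass(frozen=True)
class ClusterCollection:
    clusters: tuple[Cluster, ...]
    proteome_ids: tuple[str, ...]
    _by_id: Mapping[str, Cluster] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self._by_id is None:
            object.__setattr__(self, "_by_id",
                               {c.cluster_id: c for c in self.clusters})

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, cluster_id: str) -> Cluster:
        return self._by_id[cluster_id]

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self._by_id

    @property
    def total_proteins(self) -> int:
        return sum(c.size for c in self.clusters)

    def nonsingletons(self) -> list[Cluster]:
        return [c for c in self.clusters if c.size > 1]

    def cluster_of_protein(self) -> dict[str, str]:
        """protein ID -> cluster ID over the whole collection."""
        out: dict[str, str] = {}
        for c in self.clusters:
            for prot in c.proteins:
                out[prot] = c.cluster_id
        return out


@dataclass
class AttributeTable:
    """Proteome -> {attribute: level} map defining the taxon sets.

    The reserved attribute ``all`` places every proteome in a single
    level (also called ``all``); the reserved attribute ``TAXON`` gives
    each proteome its own level. Both are always present.
    """

    proteomes: list[str]
    attributes: list[str]
    level_of: dict[tuple[str, str], str]
    taxid_of: dict[str, str] | None = None

    def __post_init__(self):
        for p in self.proteomes:
            self.level_of.setdefault((p, RESERVED_ALL), RESERVED_ALL)
            self.level_of.setdefault((p, RESERVED_TAXON), p)
        for reserved in (RESERVED_ALL, RESERVED_TAXON):
            if reserved in self.attributes:
                self.attributes.remove(reserved)
            self.attributes.insert(0, reserved)

    def levels(self, attribute: str) -> dict[str, set[str]]:
        """level name -> set of proteome IDs, for one attribute."""
        if attribute not in self.attributes:
            raise KeyError(f"unknown attribute {attribute!r}")
        out: dict[str, set[str]] = {}
        for p in self.proteomes:
            out.setdefault(self.level_of[(p, attribute)], set()).add(p)
        return out

    def with_attribute(self, name: str,
                       level_map: Mapping[str, str]) -> "AttributeTable":
        """Return a copy with one extra attribute (proteome -> level)."""
        new_levels = dict(self.level_of)
        for p in self.proteomes:
            new_levels[(p, name)] = level_map[p]
        attrs = [a for a in self.attributes
                 if a not in (RESERVED_ALL, RESERVED_TAXON)]
        if name not in attrs:
            attrs.append(name)
        return AttributeTable(list(self.proteomes), attrs, new_levels,
                              dict(self.taxid_of) if self.taxid_of else None)


@dataclass(frozen=True)
class AnnotationTable:
    """Unique (protein, namespace, termID) records with descriptions."""

    records: Mapping[str, Mapping[tuple[str, str], str]]

    def __contains__(self, protein: str) -> bool:
        return protein in self.records

    @property
    def proteins(self) -> set[str]:
        return set(self.records)

    @property
    def namespaces(self) -> set[str]:
        return {src for terms in self.records.values() for src, _ in terms}

    def terms_of(self, protein: str,
                 namespace: str | None = None) -> list[tuple[str, str, str]]:
        """(namespace, termID, description) records for one protein."""
        out = []
        for (src, term), desc in self.records.get(protein, {}).items():
            if namespace is None or src == namespace:
                out.append((src, term, desc))
        return out

    def has_term(self, protein: str, namespace: str) -> bool:
        return any(src == namespace
                   for src, _ in self.records.get(protein, {}))


@dataclass(frozen=True)
class LengthTable:
    lengths: Mapping[str, int]

    def __contains__(self, protein: str) -> bool:
        return protein in self.lengths

    def __getitem__(self, protein: str) -> int:
        return self.lengths[protein]

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class TreeTopology:
    """Rooted topology: leaves are proteome IDs, internal nodes ``n<k>``.

    Internal node labels are assigned in preorder from the root after
    rooting (root = ``n0``). ``children`` maps every internal label to
    its child labels (internal labels or leaf names); ``leaves_under``
    is defined for internal labels and for leaves (a leaf is under
    itself).
    """

    root: str
    children: Mapping[str, tuple[str, ...]]
    leaves_under: Mapping[str, frozenset[str]]

    @property
    def internal_nodes(self) -> list[str]:
        """Internal node labels in preorder."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in self.children:
                order.append(node)
                stack.extend(reversed(self.children[node]))
        return order

    @property
    def leaves(self) -> frozenset[str]:
        return self.leaves_under[self.root]

    def mrca(self, leaf_set: Iterable[str]) -> str:
        """Label of the most recent common ancestor of the given leaves."""
        target = frozenset(leaf_set)
        missing = target - self.leaves
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        if len(target) == 1:
            return next(iter(target))
        node = self.root
        while True:
            containing = [c for c in self.children.get(node, ())
                          if target <= self.leaves_under[c]]
            if not containing:
                return node
            node = containing[0]


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_sequence_ids(path: str | Path,
                       proteome_order: Sequence[str]) -> SequenceMap:
    """Parse an OrthoFinder ``SequenceIDs.txt`` file.

    Lines are ``<proteomeIdx>_<seqIdx>: <proteinID>``. Proteome indices
    are resolved to proteome IDs positionally through *proteome_order*
    (the config-file ordering).
    """
    path = Path(path)
    entries: dict[str, tuple[str, str]] = {}
    seen_proteins: set[str] = set()
    indices: set[int] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if ": " not in line and ":" not in line:
                raise ParseError("expected '<i>_<j>: <proteinID>'",
                                 path, lineno)
            token, _, protein = line.partition(":")
            token = token.strip()
            protein = protein.strip()
            if not protein or "_" not in token:
                raise ParseError("expected '<i>_<j>: <proteinID>'",
                                 path, lineno)
            idx_str = token.split("_", 1)[0]
            try:
                idx = int(idx_str)
            except ValueError:
                raise ParseError(f"non-numeric proteome index {idx_str!r}",
                                 path, lineno) from None
            if token in entries:
                raise ParseError(f"duplicate token {token!r}", path, lineno)
            if protein in seen_proteins:
                raise ParseError(f"duplicate protein ID {protein!r}",
                                 path, lineno)
            if idx >= len(proteome_order):
                raise ParseError(
                    f"proteome index {idx} out of range for "
                    f"{len(proteome_order)} configured proteomes",
                    path, lineno)
            entries[token] = (protein, proteome_order[idx])
            seen_proteins.add(protein)
            indices.add(idx)
    if indices and indices != set(range(max(indices) + 1)):
        raise ParseError("proteome indices are not a contiguous 0-based "
                         f"range: {sorted(indices)}", path)
    return SequenceMap(entries)


def parse_clustering(path: str | Path, seqmap: SequenceMap,
                     infer_singletons: bool = False) -> ClusterCollection:
    """Parse an orthogroup file (``<clusterID>: <member> ...``).

    Members may be internal tokens (``0_0``, OrthoFinder working files)
    or raw protein IDs (OrthoMCL-style); the dialect is auto-detected
    from the first member token of the file. With *infer_singletons*,
    proteins present in *seqmap* but absent from the file are appended
    as synthetic singleton clusters ``singleton_<k>``.
    """
    path = Path(path)
    protein_to_proteome = {prot: pid for prot, pid in seqmap.entries.values()}
    use_tokens: bool | None = None
    clusters: list[Cluster] = []
    seen_ids: set[str] = set()
    seen_proteins: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError("expected '<clusterID>: <member> ...'",
                                 path, lineno)
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            toks = rest.split()
            if not toks:
                raise ParseError(f"cluster {cid!r} has no members",
                                 path, lineno)
            if cid in seen_ids:
                raise ParseError(f"duplicate cluster ID {cid!r}", path, lineno)
            seen_ids.add(cid)
            if use_tokens is None:
                use_tokens = toks[0] in seqmap
            members: dict[str, list[str]] = {}
            for tok in toks:
                if use_tokens:
                    if tok not in seqmap:
                        raise ParseError(
                            f"unknown sequence token {tok!r}", path, lineno)
                    protein, proteome = seqmap.entries[tok]
                else:
                    if tok not in protein_to_proteome:
                        raise ParseError(
                            f"unknown protein ID {tok!r}", path, lineno)
                    protein, proteome = tok, protein_to_proteome[tok]
                if protein in seen_proteins:
                    raise ParseError(
                        f"protein {protein!r} appears in two clusters",
                        path, lineno)
                seen_proteins.add(protein)
                members.setdefault(proteome, []).append(protein)
            clusters.append(Cluster(cid, {p: tuple(v)
                                          for p, v in members.items()}))
    if infer_singletons:
        k = 0
        for protein, proteome in seqmap.entries.values():
            if protein not in seen_proteins:
                clusters.append(Cluster(f"singleton_{k}",
                                        {proteome: (protein,)}))
                k += 1
    proteome_ids = tuple(seqmap.proteome_ids)
    return ClusterCollection(tuple(clusters), proteome_ids)


def write_clustering(clusters: ClusterCollection, path: str | Path) -> None:
    """Write a collection back to orthogroup format (raw protein IDs)."""
    with Path(path).open("w") as fh:
        for c in clusters:
            fh.write(f"{c.cluster_id}: {' '.join(c.proteins)}\n")


def parse_config(path: str | Path, delimiter: str = ",") -> AttributeTable:
    """Parse the taxon-set config table.

    First column ``#IDX``/``IDX`` (ignored beyond ordering), second
    ``TAXON`` (proteome ID); remaining columns are attribute names. An
    optional ``TAXID`` column carries NCBI TaxIDs. The reserved
    attributes ``all`` and ``TAXON`` are injected automatically.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError("empty config file", path)
    header = [h.strip() for h in lines[0].split(delimiter)]
    if header[0].lstrip("#").strip() not in ("IDX", ""):
        raise ParseError(
            f"first column must be '#IDX'/'IDX', got {header[0]!r}", path, 1)
    if len(header) < 2 or header[1] != "TAXON":
        raise ParseError("second column must be 'TAXON'", path, 1)
    attr_cols = header[2:]
    attributes = [a for a in attr_cols if a != "TAXID"]
    taxid_idx = header.index("TAXID") if "TAXID" in header else None

    proteomes: list[str] = []
    level_of: dict[tuple[str, str], str] = {}
    taxid_of: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], 2):
        cells = [c.strip() for c in line.split(delimiter)]
        if len(cells) != len(header):
            raise ParseError(
                f"expected {len(header)} cells, got {len(cells)}",
                path, lineno)
        proteome = cells[1]
        if not proteome:
            raise ParseError("empty TAXON cell", path, lineno)
        if proteome in proteomes:
            raise ParseError(f"duplicate proteome ID {proteome!r}",
                             path, lineno)
        proteomes.append(proteome)
        for col, cell in zip(header[2:], cells[2:]):
            if col == "TAXID":
                if cell:
                    taxid_of[proteome] = cell
                continue
            if not cell:
                raise ParseError(
                    f"missing level for attribute {col!r}", path, lineno)
            level_of[(proteome, col)] = cell
    return AttributeTable(proteomes, attributes, level_of,
                          taxid_of or None)


#: InterProScan columns: accession, MD5, length, analysis, signature acc,
#: signature desc, start, stop, score, status, date, [IPR acc, IPR desc, [GO]]
_IPS_MIN_COLS = 11
_IPS_MAX_COLS = 15


def parse_functional_annotation(path: str | Path) -> AnnotationTable:
    """Parse an InterProScan TSV into a collapsed annotation table.

    One record per unique (protein, namespace, termID): the analysis
    column is the namespace for signature hits (Pfam, SignalP_Euk,
    PRINTS, ...), the InterPro accession column yields namespace
    ``IPR``, and the GO column (split on ``|``) yields namespace ``GO``.
    Repeated domain hits of the same signature collapse to one record.
    """
    path = Path(path)
    records: dict[str, dict[tuple[str, str], str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            cells = raw.rstrip("\n").split("\t")
            if not (_IPS_MIN_COLS <= len(cells) <= _IPS_MAX_COLS):
                raise ParseError(
                    f"expected {_IPS_MIN_COLS}-{_IPS_MAX_COLS} tab-separated "
                    f"columns, got {len(cells)}", path, lineno)
            protein = cells[0]
            analysis = cells[3]
            sig_acc = cells[4]
            sig_desc = cells[5] if len(cells) > 5 else ""
            per = records.setdefault(protein, {})
            if sig_acc:
                per.setdefault((analysis, sig_acc), sig_desc)
            if len(cells) > 11 and cells[11] and cells[11] != "-":
                ipr_desc = cells[12] if len(cells) > 12 else ""
                per.setdefault((NAMESPACE_IPR, cells[11]), ipr_desc)
            if len(cells) > 13 and cells[13] and cells[13] != "-":
                for go in cells[13].split("|"):
                    go = go.strip()
                    if go:
                        per.setdefault((NAMESPACE_GO, go), "")
    return AnnotationTable(records)


def read_fasta_lengths(paths: Iterable[str | Path]) -> LengthTable:
    """Residue counts per protein from proteome FASTA files.

    The first whitespace-delimited header token is the protein ID; a
    terminal ``*`` (stop) is stripped before counting. Duplicate IDs
    across files are an error.
    """
    lengths: dict[str, int] = {}
    for p in paths:
        p = Path(p)
        with p.open() as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                pid = rec.id
                if pid in lengths:
                    raise ParseError(f"duplicate protein ID {pid!r}", p)
                seq = str(rec.seq)
                if seq.endswith("*"):
                    seq = seq[:-1]
                if not seq:
                    raise ParseError(f"empty sequence for {pid!r}", p)
                lengths[pid] = len(seq)
    return LengthTable(lengths)


def parse_tree(path: str | Path, outgroups: Sequence[str],
               attrs: AttributeTable | None = None) -> TreeTopology:
    """Parse a Newick topology and root it on the outgroup split.

    Internal nodes are labelled ``n0..nK`` in preorder from the root;
    per-node descendant-leaf sets are precomputed. If *attrs* is given,
    every leaf must be a configured proteome.
    """
    path = Path(path)
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(outgroups) - leaf_labels
    if missing:
        raise ParseError(f"outgroup(s) not in tree: {sorted(missing)}", path)
    if attrs is not None:
        unknown = leaf_labels - set(attrs.proteomes)
        if unknown:
            raise ParseError(
                f"tree leaves not in config: {sorted(unknown)}", path)
    if outgroups:
        if set(outgroups) == leaf_labels:
            raise ParseError("outgroup set covers every leaf", path)
        mrca = tree.mrca(taxon_labels=list(outgroups))
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        else:
            # outgroup leaves span the current root: root on the
            # complement clade instead (same split).
            rest = leaf_labels - set(outgroups)
            alt = tree.mrca(taxon_labels=list(rest))
            if alt is not tree.seed_node:
                tree.reroot_at_edge(alt.edge, update_bipartitions=False)
    tree.suppress_unifurcations()

    children: dict[str, tuple[str, ...]] = {}
    leaves_under: dict[str, frozenset[str]] = {}
    counter = 0
    labels: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[id(node)] = node.taxon.label
        else:
            labels[id(node)] = f"n{counter}"
            counter += 1
    # postorder pass for leaf sets, then record children
    for node in tree.postorder_node_iter():
        lab = labels[id(node)]
        if node.is_leaf():
            leaves_under[lab] = frozenset({lab})
        else:
            kids = [labels[id(c)] for c in node.child_nodes()]
            if len(kids) < 2:
                raise ParseError(f"internal node {lab} has < 2 children",
                                 path)
            children[lab] = tuple(kids)
            leaves_under[lab] = frozenset().union(
                *(leaves_under[k] for k in kids))
    return TreeTopology(labels[id(tree.seed_node)], children, leaves_under)


# ---------------------------------------------------------------------------
# NCBI taxonomy rank expansion
# ---------------------------------------------------------------------------

def _parse_dmp(path: Path) -> Iterable[list[str]]:
    with path.open() as fh:
        for line in fh:
            line = line.rstrip()
            if line.endswith("|"):
                line = line[:-1]
            yield [c.strip() for c in line.split("\t|\t")]


def expand_taxonomy_ranks(attrs: AttributeTable, taxdump_dir: str | Path,
                          ranks: Sequence[str] = ("phylum", "order", "genus"),
                          ) -> AttributeTable:
    """Add one attribute per taxonomic rank from NCBI taxdump files.

    For each proteome with a TaxID, the lineage is walked through
    ``nodes.dmp`` to the ancestor of the requested rank; the level is
    that ancestor's scientific name from ``names.dmp``, or ``undef``
    when the lineage lacks the rank or the TaxID is unknown.
    """
    if attrs.taxid_of is None:
        raise ValueError("config table has no TAXID column; "
                         "cannot expand taxonomy ranks")
    taxdump_dir = Path(taxdump_dir)
    parent: dict[str, str] = {}
    rank_of: dict[str, str] = {}
    for cells in _parse_dmp(taxdump_dir / "nodes.dmp"):
        taxid, par, rank = cells[0], cells[1], cells[2]
        parent[taxid] = par
        rank_of[taxid] = rank
    name_of: dict[str, str] = {}
    for cells in _parse_dmp(taxdump_dir / "names.dmp"):
        if len(cells) >= 4 and cells[3] == "scientific name":
            name_of[cells[0]] = cells[1]

    out = attrs
    for rank in ranks:
        level_map: dict[str, str] = {}
        for proteome in attrs.proteomes:
            taxid = (attrs.taxid_of or {}).get(proteome)
            level = "undef"
            if taxid is None or taxid not in parent:
                if taxid is not None:
                    warnings.warn(
                        f"TaxID {taxid} ({proteome}) absent from taxdump; "
                        f"rank {rank!r} set to 'undef'")
            else:
                node = taxid
                while True:
                    if rank_of.get(node) == rank:
                        level = name_of.get(node, node)
                        break
                    nxt = parent.get(node)
                    if nxt is None or nxt == node:
                        break
                    node = nxt
            level_map[proteome] = level
        out = out.with_attribute(rank, level_map)
    return out
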