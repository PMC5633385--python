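"""Phylogeny-aware cluster analysis under Dollo parsimony.

Dollo parsimony assumes a gene family arises once and may be lost many
times. A cluster is synapomorphic for a tree node when (a) only
proteomes descending from that node are members, and (b) every child of
the node contributes at least one member — so the gain maps to the
branch leading to the node, regardless of later losses. Because losses
are not penalised, synapomorphies are further classified by taxon
coverage (member proteomes / leaves under the node):

* ``complete_presence`` — coverage 1.0;
* ``partial_absence``   — node_taxon_cov <= coverage < 1;
* ``below_threshold``   — coverage below node_taxon_cov (written to the
  detailed output but excluded from headline counts).

Singleton and single-proteome clusters are apomorphies (private to one
proteome) and are listed separately, never assigned to internal nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from clusterkin.annotation import (
    CoverageParams,
    RepresentativeAnnotation,
    representative_annotation,
)
from clusterkin.formats_io import (
    AnnotationTable,
    Cluster,
    ClusterCollection,
    TreeTopology,
)

SYNAPOMORPHY_CLASSES = ("complete_presence", "partial_absence",
                        "below_threshold")


@dataclass(frozen=True)
class SynapomorphyRecord:
    cluster_id: str
    node_id: str
    coverage: float           # member proteomes / leaves under node
    cls: str                  # one of SYNAPOMORPHY_CLASSES
    child_support: Mapping[str, bool]

    def __post_init__(self):
        if self.cls not in SYNAPOMORPHY_CLASSES:
            raise ValueError(f"bad synapomorphy class {self.cls!r}")


@dataclass(frozen=True)
class NodeAnnotationParams:
    node_taxon_cov: float = 0.75
    domain_taxon_cov: float = 0.75
    domain_protein_cov: float = 0.75

    def __post_init__(self):
        for v in (self.node_taxon_cov, self.domain_taxon_cov,
                  self.domain_protein_cov):
            if not (0.0 <= v <= 1.0):
                raise ValueError("all coverages must be in [0, 1]")


def _classify_coverage(coverage: float, node_taxon_cov: float) -> str:
    if coverage == 1.0:
        return "complete_presence"
    if coverage >= node_taxon_cov:
        return "partial_absence"
    return "below_threshold"


def assign_synapomorphy(cluster: Cluster, tree: TreeTopology,
                        node_taxon_cov: float = 0.75,
                        ) -> SynapomorphyRecord | None:
    """Dollo assignment of one cluster to its gain node, if any.

    Implementation: the only node that can satisfy "members are a
    subset of the node's leaves AND every child contributes a member"
    is the MRCA of the member proteomes, so the MRCA is located and the
    child-support condition verified there. Returns ``None`` for
    apomorphic clusters (single proteome) and clusters whose members
    include proteomes absent from the tree.
    """
    proteomes = cluster.proteomes
    if len(proteomes) < 2:
        return None
    if not proteomes <= tree.leaves:
        return None
    node = tree.mrca(proteomes)
    children = tree.children.get(node)
    if children is None:  # MRCA is a leaf: impossible for >= 2 proteomes
        return None
    child_support = {c: bool(proteomes & tree.leaves_under[c])
                     for c in children}
    if not all(child_support.values()):
        # cannot happen at the MRCA by definition; kept as a guard
        return None
    coverage = len(proteomes) / len(tree.leaves_under[node])
    return SynapomorphyRecord(cluster.cluster_id, node, coverage,
                              _classify_coverage(coverage, node_taxon_cov),
                              child_support)


def infer_synapomorphies(tree: TreeTopology, clusters: ClusterCollection,
                         node_taxon_cov: float = 0.75,
                         ) -> dict[str, list[SynapomorphyRecord]]:
    """Synapomorphic clusters per internal node.

    Every multi-proteome cluster is assigned to at most one node (its
    gain branch under Dollo parsimony). Clusters spanning proteomes not
    present in the tree are excluded with a warning — a tree/config
    mismatch is a user error, not silently dropped data.
    """
    import warnings

    out: dict[str, list[SynapomorphyRecord]] = {
        n: [] for n in tree.internal_nodes}
    for c in clusters:
        if len(c.proteomes) >= 2 and not c.proteomes <= tree.leaves:
            warnings.warn(
                f"cluster {c.cluster_id} spans proteomes missing from the "
                f"tree ({sorted(c.proteomes - tree.leaves)}); excluded")
            continue
        rec = assign_synapomorphy(c, tree, node_taxon_cov)
        if rec is not None:
            out[rec.node_id].append(rec)
    return out


def count_synapomorphies(records: Mapping[str, Sequence[SynapomorphyRecord]],
                         include_below_threshold: bool = False,
                         ) -> dict[str, int]:
    """Headline per-node counts (complete presence + partial absence)."""
    return {
        node: sum(1 for r in recs
                  if include_below_threshold or r.cls != "below_threshold")
        for node, recs in records.items()}


def list_apomorphies(clusters: ClusterCollection,
                     ) -> dict[str, dict[str, list[str]]]:
    """Per-proteome apomorphy lists.

    ``singleton`` apomorphies are size-1 clusters; ``nonsingleton``
    apomorphies are clusters of two or more proteins drawn from exactly
    one proteome. Proteomes without apomorphies get empty lists.
    """
    out: dict[str, dict[str, list[str]]] = {
        p: {"singleton": [], "nonsingleton": []}
        for p in clusters.proteome_ids}
    for c in clusters:
        if c.proteome_count != 1:
            continue
        proteome = next(iter(c.proteomes))
        key = "singleton" if c.size == 1 else "nonsingleton"
        out[proteome][key].append(c.cluster_id)
    return out


def node_annotation_summary(node: str,
                            records: Mapping[str, Sequence[SynapomorphyRecord]],
                            clusters: ClusterCollection,
                            annotations: AnnotationTable,
                            params: NodeAnnotationParams = NodeAnnotationParams(),
                            namespace: str = "IPR",
                            ) -> dict:
    """Representative annotation of a node's synapomorphic clusters.

    Considers synapomorphies at or above ``node_taxon_cov`` (complete
    presence and partial absence). The summary fraction of annotated
    synapomorphies is ``None`` (N/A) when the node has none.
    """
    cov_params = CoverageParams(params.domain_taxon_cov,
                                params.domain_protein_cov)
    recs = [r for r in records.get(node, ())
            if r.cls != "below_threshold"]
    per_cluster: dict[str, list[RepresentativeAnnotation]] = {}
    annotated = 0
    for r in recs:
        reps = representative_annotation(clusters[r.cluster_id], annotations,
                                         cov_params, namespace)
        per_cluster[r.cluster_id] = reps
        if reps:
            annotated += 1
    return {
        "node": node,
        "synapomorphy_count": len(recs),
        "annotated_count": annotated,
        "annotated_fraction": (annotated / len(recs)) if recs else None,
        "representative": per_cluster,
    }


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_synapomorphies(records: Mapping[str, Sequence[SynapomorphyRecord]],
                         clusters: ClusterCollection,
                         annotations: AnnotationTable | None,
                         params: NodeAnnotationParams,
                         path: str | Path, namespace: str = "IPR") -> None:
    """``tree.synapomorphies.tsv``: node, cluster, coverage, class,
    representative annotation (all classes, including below_threshold)."""
    cov_params = CoverageParams(params.domain_taxon_cov,
                                params.domain_protein_cov)
    with Path(path).open("w") as fh:
        fh.write("#node\tcluster_id\ttaxon_coverage\tclass\t"
                 "representative_annotation\n")
        for node in sorted(records):
            for r in sorted(records[node], key=lambda r: r.cluster_id):
                rep = "N/A"
                if annotations is not None:
                    reps = representative_annotation(
                        clusters[r.cluster_id], annotations, cov_params,
                        namespace)
                    if reps:
                        rep = ";".join(f"{x.term_id}({x.description})"
                                       for x in reps)
                fh.write(f"{node}\t{r.cluster_id}\t{r.coverage:.4f}\t"
                         f"{r.cls}\t{rep}\n")


def write_node_summary(tree: TreeTopology,
                       records: Mapping[str, Sequence[SynapomorphyRecord]],
                       clusters: ClusterCollection,
                       annotations: AnnotationTable | None,
                       params: NodeAnnotationParams,
                       path: str | Path, namespace: str = "IPR") -> None:
    """``tree.node_summary.tsv``: per-node synapomorphy tallies."""
    with Path(path).open("w") as fh:
        fh.write("#node\tleaves\tcomplete_presence\tpartial_absence\t"
                 "below_threshold\tannotated_fraction\n")
        for node in tree.internal_nodes:
            recs = records.get(node, [])
            by_cls = {cls: sum(1 for r in recs if r.cls == cls)
                      for cls in SYNAPOMORPHY_CLASSES}
            frac = "N/A"
            if annotations is not None:
                summ = node_annotation_summary(node, records, clusters,
                                               annotations, params,
                                               namespace)
                if summ["annotated_fraction"] is not None:
                    frac = f"{100 * summ['annotated_fraction']:.2f}"
            fh.write(f"{node}\t{len(tree.leaves_under[node])}\t"
                     f"{by_cls['complete_presence']}\t"
                     f"{by_cls['partial_absence']}\t"
                     f"{by_cls['below_threshold']}\t{frac}\n")
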