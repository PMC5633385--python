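"""Core cluster/taxon-set model: cluster typing, matrices, metrics.

Under each attribute, the attribute's levels partition the proteomes
into taxon sets and every cluster receives exactly one type:

* ``singleton`` — exactly one protein;
* ``specific`` — two or more proteins, all from a single taxon set;
* ``shared``   — proteins from two or more taxon sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from clusterkin.formats_io import (
    AnnotationTable,
    AttributeTable,
    Cluster,
    ClusterCollection,
    LengthTable,
    NAMESPACE_SIGNALP,
)

CLUSTER_TYPES = ("singleton", "specific", "shared")


@dataclass(frozen=True)
class TaxonSet:
    """One level of an attribute: a named, nonempty set of proteomes."""

    attribute: str
    level: str
    proteomes: frozenset[str]

    def __post_init__(self):
        if not self.proteomes:
            raise ValueError(f"taxon set {self.attribute}={self.level} "
                             "has no proteomes")

    def __len__(self) -> int:
        return len(self.proteomes)


def taxon_sets(attrs: AttributeTable, attribute: str) -> list[TaxonSet]:
    """All taxon sets (levels) of one attribute, in stable level order."""
    return [TaxonSet(attribute, level, frozenset(members))
            for level, members in sorted(attrs.levels(attribute).items())]


@dataclass(frozen=True)
class ClusterTypeRecord:
    cluster_id: str
    attribute: str
    cluster_type: str
    covered_levels: frozenset[str]
    present: Mapping[str, bool]

    def __post_init__(self):
        if self.cluster_type not in CLUSTER_TYPES:
            raise ValueError(f"bad cluster type {self.cluster_type!r}")


def classify_cluster(cluster: Cluster,
                     sets: Iterable[TaxonSet]) -> ClusterTypeRecord:
    """Assign a cluster type under one attribute's taxon sets.

    The sets must jointly cover every proteome contributing to the
    cluster (they partition the configured proteome list).
    """
    sets = list(sets)
    attribute = sets[0].attribute
    present = {s.level: bool(cluster.proteomes & s.proteomes) for s in sets}
    covered = frozenset(lv for lv, p in present.items() if p)
    uncovered = cluster.proteomes - frozenset().union(
        *(s.proteomes for s in sets))
    if uncovered:
        raise ValueError(
            f"cluster {cluster.cluster_id}: proteomes {sorted(uncovered)} "
            f"not covered by attribute {attribute!r}")
    if cluster.size == 1:
        ctype = "singleton"
    elif len(covered) == 1:
        ctype = "specific"
    else:
        ctype = "shared"
    return ClusterTypeRecord(cluster.cluster_id, attribute, ctype,
                             covered, present)


def classify_clusters(clusters: ClusterCollection, attrs: AttributeTable,
                      attribute: str) -> list[ClusterTypeRecord]:
    sets = taxon_sets(attrs, attribute)
    return [classify_cluster(c, sets) for c in clusters]


def build_matrices(clusters: ClusterCollection, attrs: AttributeTable,
                   attribute: str
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cluster x level count matrix, presence matrix, per-level summary.

    Returns ``(counts, presence, summary)``: *counts* holds protein
    counts per cluster and level, *presence* is its boolean mask, and
    *summary* tallies cluster and protein counts per level split by
    cluster type (singleton / specific / shared).
    """
    sets = taxon_sets(attrs, attribute)
    level_names = [s.level for s in sets]
    index = [c.cluster_id for c in clusters]
    counts = np.zeros((len(index), len(sets)), dtype=int)
    for i, c in enumerate(clusters):
        for j, s in enumerate(sets):
            counts[i, j] = sum(c.count(p) for p in s.proteomes)
    counts_df = pd.DataFrame(counts, index=index, columns=level_names)
    presence_df = counts_df > 0

    records = classify_clusters(clusters, attrs, attribute)
    rows = []
    for s in sets:
        row: dict[str, object] = {"level": s.level,
                                  "proteome_count": len(s)}
        for ctype in CLUSTER_TYPES:
            ncl = npr = 0
            for c, rec in zip(clusters, records):
                if rec.cluster_type == ctype and rec.present[s.level]:
                    ncl += 1
                    npr += sum(c.count(p) for p in s.proteomes)
            row[f"{ctype}_clusters"] = ncl
            row[f"{ctype}_proteins"] = npr
        row["total_clusters"] = sum(row[f"{t}_clusters"]  # type: ignore[misc]
                                    for t in CLUSTER_TYPES)
        row["total_proteins"] = sum(row[f"{t}_proteins"]  # type: ignore[misc]
                                    for t in CLUSTER_TYPES)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("level")
    return counts_df, presence_df, summary


@dataclass(frozen=True)
class ClusterMetrics:
    cluster_id: str
    mean_length: float | None
    sd_length: float | None          # sample SD; None for singletons / no data
    secreted_fraction: float
    entropy: Mapping[str, float | None]  # per-namespace Shannon entropy, bits


def annotation_entropy(cluster: Cluster, annotations: AnnotationTable,
                       namespace: str) -> float | None:
    """Shannon entropy (bits) of term incidence within a cluster.

    Each term's weight is the number of cluster members carrying it,
    normalised over all terms of the namespace; ``None`` (reported as
    N/A) when no member has any annotation in the namespace.
    """
    term_counts: dict[str, int] = {}
    for prot in cluster.proteins:
        for src, term, _ in annotations.terms_of(prot, namespace):
            term_counts[term] = term_counts.get(term, 0) + 1
    if not term_counts:
        return None
    total = sum(term_counts.values())
    return -sum((c / total) * math.log2(c / total)
                for c in term_counts.values()) + 0.0


def compute_cluster_metrics(cluster: Cluster,
                            lengths: LengthTable | None = None,
                            annotations: AnnotationTable | None = None,
                            entropy_namespaces: Iterable[str] = ("Pfam", "GO"),
                            ) -> ClusterMetrics:
    """Per-cluster length, secretion, and annotation-entropy metrics.

    Length statistics use the sample (n-1) standard deviation; the SD of
    a singleton cluster is undefined and reported as ``None``/N/A.
    ``secreted_fraction`` is the fraction of members carrying at least
    one signal-peptide (SignalP_Euk) record.
    """
    mean_len: float | None = None
    sd_len: float | None = None
    if lengths is not None:
        vals = []
        for prot in cluster.proteins:
            if prot in lengths:
                vals.append(lengths[prot])
            else:
                warnings.warn(f"no length for protein {prot!r}; "
                              "excluded from length statistics")
        if vals:
            mean_len = float(np.mean(vals))
            sd_len = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    secreted = 0.0
    entropy: dict[str, float | None] = {}
    if annotations is not None:
        n_sec = sum(1 for prot in cluster.proteins
                    if annotations.has_term(prot, NAMESPACE_SIGNALP))
        secreted = n_sec / cluster.size
        for ns in entropy_namespaces:
            entropy[ns] = annotation_entropy(cluster, annotations, ns)
    return ClusterMetrics(cluster.cluster_id, mean_len, sd_len,
                          secreted, entropy)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def _fmt(x: object) -> str:
    if x is None:
        return "N/A"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_cluster_types(records: Iterable[ClusterTypeRecord],
                        counts: pd.DataFrame, path) -> None:
    """``<attr>.cluster_types.tsv``: cluster, type, covered levels, counts."""
    records = list(records)
    levels = list(counts.columns)
    with open(path, "w") as fh:
        fh.write("#cluster_id\tcluster_type\tcovered_levels\t"
                 + "\t".join(f"count_{lv}" for lv in levels) + "\n")
        for rec in records:
            row = counts.loc[rec.cluster_id]
            fh.write("\t".join(
                [rec.cluster_id, rec.cluster_type,
                 ",".join(sorted(rec.covered_levels))]
                + [str(int(row[lv])) for lv in levels]) + "\n")


def write_level_summary(summary: pd.DataFrame, path) -> None:
    """``<attr>.level_summary.tsv`` with per-level type tallies."""
    out = summary.reset_index()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(out.columns) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
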