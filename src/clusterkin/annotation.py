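"""Cluster-level functional annotation aggregation.

There is no accepted standard for assigning a single functional label
to a protein cluster. The approach here lists every term of a namespace
with its coverage inside the cluster, and promotes to *representative*
status those terms meeting two thresholds:

* ``domain_taxon_cov``  — minimum fraction of the cluster's proteomes
  with at least one member annotated with the term;
* ``domain_protein_cov`` — minimum fraction of the cluster's proteins
  annotated with the term.

A genes-of-interest report maps query protein/gene IDs onto clusters
and summarises per-proteome counts and representative annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from clusterkin.formats_io import (
    AnnotationTable,
    AttributeTable,
    Cluster,
    ClusterCollection,
)


@dataclass(frozen=True)
class CoverageParams:
    domain_taxon_cov: float = 0.75
    domain_protein_cov: float = 0.75

    def __post_init__(self):
        for v in (self.domain_taxon_cov, self.domain_protein_cov):
            if not (0.0 <= v <= 1.0):
                raise ValueError("coverage thresholds must be in [0, 1]")


@dataclass(frozen=True)
class TermCoverage:
    term_id: str
    description: str
    taxon_cov: Fraction
    protein_cov: Fraction
    protein_count: int
    proteome_count: int


@dataclass(frozen=True)
class RepresentativeAnnotation:
    cluster_id: str
    namespace: str
    term_id: str
    description: str
    taxon_cov: float
    protein_cov: float


def term_coverages(cluster: Cluster, annotations: AnnotationTable,
                   namespace: str) -> list[TermCoverage]:
    """Per-term protein and proteome coverage within one cluster.

    Coverages are exact rationals: ``taxon_cov`` = proteomes with >= 1
    annotated member / proteomes in cluster; ``protein_cov`` =
    annotated members / cluster size. Terms carried by no member are
    absent from the list.
    """
    per_term_proteins: dict[str, set[str]] = {}
    per_term_proteomes: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for proteome, prots in cluster.members.items():
        for prot in prots:
            for _, term, d in annotations.terms_of(prot, namespace):
                per_term_proteins.setdefault(term, set()).add(prot)
                per_term_proteomes.setdefault(term, set()).add(proteome)
                if d and not desc.get(term):
                    desc[term] = d
    out = []
    for term in sorted(per_term_proteins):
        npr = len(per_term_proteins[term])
        npm = len(per_term_proteomes[term])
        out.append(TermCoverage(
            term, desc.get(term, ""),
            Fraction(npm, cluster.proteome_count),
            Fraction(npr, cluster.size), npr, npm))
    return out


def representative_annotation(cluster: Cluster, annotations: AnnotationTable,
                              params: CoverageParams = CoverageParams(),
                              namespace: str = "IPR",
                              ) -> list[RepresentativeAnnotation]:
    """Terms passing both coverage thresholds, best-covered first.

    Ranked by protein coverage (desc), then taxon coverage (desc), then
    term ID (asc). An empty list means the cluster received no
    representative annotation in this namespace at these thresholds.
    """
    covs = term_coverages(cluster, annotations, namespace)
    kept = [tc for tc in covs
            if tc.taxon_cov >= params.domain_taxon_cov
            and tc.protein_cov >= params.domain_protein_cov]
    kept.sort(key=lambda tc: (-tc.protein_cov, -tc.taxon_cov, tc.term_id))
    return [RepresentativeAnnotation(cluster.cluster_id, namespace,
                                     tc.term_id, tc.description,
                                     float(tc.taxon_cov),
                                     float(tc.protein_cov))
            for tc in kept]


def write_domain_annotation(clusters: ClusterCollection,
                            annotations: AnnotationTable,
                            params: CoverageParams, namespace: str,
                            path: str | Path) -> int:
    """``cluster_domain_annotation.<namespace>.tsv``; returns the number
    of clusters with at least one representative term."""
    annotated = 0
    with Path(path).open("w") as fh:
        fh.write("#cluster_id\tnamespace\tterm_id\tdescription\t"
                 "taxon_cov\tprotein_cov\n")
        for c in clusters:
            reps = representative_annotation(c, annotations, params,
                                             namespace)
            if reps:
                annotated += 1
            for r in reps:
                fh.write(f"{r.cluster_id}\t{r.namespace}\t{r.term_id}\t"
                         f"{r.description}\t{r.taxon_cov:.4f}\t"
                         f"{r.protein_cov:.4f}\n")
    return annotated


# ---------------------------------------------------------------------------
# genes of interest
# ---------------------------------------------------------------------------

#: isoform-suffix separators accepted when matching a gene ID against
#: protein IDs (gene `g` matches proteins `g`, `g.1`, `g-RA`, `g_t1`, ...)
_GENE_SEPARATORS = (".", "-", "_t")


def _match_ids(query: str, proteins: Iterable[str]) -> set[str]:
    hits = set()
    for prot in proteins:
        if prot == query:
            hits.add(prot)
        else:
            for sep in _GENE_SEPARATORS:
                if prot.startswith(query + sep):
                    hits.add(prot)
                    break
    return hits


@dataclass(frozen=True)
class GeneOfInterestRow:
    cluster_id: str
    query_hits: tuple[str, ...]              # query IDs hitting the cluster
    matched_proteins: tuple[str, ...]
    per_proteome_counts: dict[str, int]
    representative: tuple[RepresentativeAnnotation, ...]


@dataclass(frozen=True)
class GenesOfInterestReport:
    rows: tuple[GeneOfInterestRow, ...]
    unmatched: tuple[str, ...]


def genes_of_interest_report(ids: Sequence[str],
                             clusters: ClusterCollection,
                             annotations: AnnotationTable | None,
                             attrs: AttributeTable,
                             params: CoverageParams = CoverageParams(),
                             namespace: str = "IPR",
                             ) -> GenesOfInterestReport:
    """Map query protein or gene IDs onto clusters.

    Each query matches protein IDs exactly or as gene-ID prefixes with
    an isoform separator. For every cluster hit by at least one query,
    the row records which queries hit it, the matched proteins, the
    per-proteome protein counts of the whole cluster, and its
    representative annotation. Unmatched queries are reported, not
    fatal.
    """
    if not ids:
        raise ValueError("empty gene-of-interest ID list")
    prot_to_cluster = clusters.cluster_of_protein()
    all_proteins = list(prot_to_cluster)
    per_cluster_queries: dict[str, list[str]] = {}
    per_cluster_matches: dict[str, set[str]] = {}
    unmatched: list[str] = []
    for query in ids:
        hits = _match_ids(query, all_proteins)
        if not hits:
            unmatched.append(query)
            continue
        for prot in hits:
            cid = prot_to_cluster[prot]
            per_cluster_queries.setdefault(cid, [])
            if query not in per_cluster_queries[cid]:
                per_cluster_queries[cid].append(query)
            per_cluster_matches.setdefault(cid, set()).add(prot)
    rows = []
    for cid in sorted(per_cluster_queries):
        cluster = clusters[cid]
        counts = {p: cluster.count(p) for p in attrs.proteomes}
        reps: tuple[RepresentativeAnnotation, ...] = ()
        if annotations is not None:
            reps = tuple(representative_annotation(cluster, annotations,
                                                   params, namespace))
        rows.append(GeneOfInterestRow(
            cid, tuple(per_cluster_queries[cid]),
            tuple(sorted(per_cluster_matches[cid])), counts, reps))
    return GenesOfInterestReport(tuple(rows), tuple(unmatched))


def write_genes_of_interest(report: GenesOfInterestReport,
                            attrs: AttributeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#cluster_id\tquery_hits\tmatched_proteins\t"
                 + "\t".join(f"count_{p}" for p in attrs.proteomes)
                 + "\trepresentative_annotation\n")
        for row in report.rows:
            rep = ";".join(f"{r.term_id}({r.description})"
                           for r in row.representative) or "N/A"
            fh.write(f"{row.cluster_id}\t{','.join(row.query_hits)}\t"
                     f"{','.join(row.matched_proteins)}\t"
                     + "\t".join(str(row.per_proteome_counts[p])
                                 for p in attrs.proteomes)
                     + f"\t{rep}\n")
        if report.unmatched:
            fh.write("#unmatched\t" + ",".join(report.unmatched) + "\n")
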