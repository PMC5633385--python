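"""Map genes of interest onto clusters.

Given protein or gene IDs from a reference species, report the clusters
containing them, their per-proteome copy counts and representative
functional annotation — the entry point for directed homolog surveys.
"""

from clusterkin import toy3_fixture
from clusterkin.annotation import genes_of_interest_report

toy = toy3_fixture()
report = genes_of_interest_report(["a1", "a3", "nonexistent_gene"],
                                  toy.clusters, toy.annotations, toy.attrs)
for row in report.rows:
    counts = " ".join(f"{p}:{c}" for p, c in row.per_proteome_counts.items())
    rep = (";".join(r.term_id for r in row.representative) or "none")
    print(f"{row.cluster_id}: queries={','.join(row.query_hits)} "
          f"counts=[{counts}] annotation={rep}")
print("unmatched queries:", ", ".join(report.unmatched) or "none")

# a1 lands in the universal cluster OG0 (one copy per proteome, IPR
# annotated); a3 in the A-specific expansion OG2; unknown IDs are
# reported rather than fatal.
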