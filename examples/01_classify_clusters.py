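"""Classify orthology clusters against taxon sets.

Uses the embedded three-proteome worked example: every cluster is typed
as singleton, specific, or shared, once per attribute. The same cluster
can be specific under one grouping and shared under another — that is
the point of user-defined taxon sets.
"""

from clusterkin import toy3_fixture
from clusterkin.model import build_matrices, classify_clusters

toy = toy3_fixture()
for attribute in ("TAXON", "host"):
    records = classify_clusters(toy.clusters, toy.attrs, attribute)
    print(f"attribute {attribute!r}:")
    for rec in records:
        print(f"  {rec.cluster_id}: {rec.cluster_type:9s} "
              f"levels={sorted(rec.covered_levels)}")
    _, _, summary = build_matrices(toy.clusters, toy.attrs, attribute)
    print(summary[["singleton_clusters", "specific_clusters",
                   "shared_clusters"]].to_string())
    print()

# OG1 (one protein each from A and B) is shared under TAXON but
# specific to the "human" host set, which groups A and B together.
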