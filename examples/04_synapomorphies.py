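"""Dollo-parsimony synapomorphies on a tree topology.

A cluster is synapomorphic for a node when only proteomes under that
node are members and every child contributes at least one — the gene
family was gained once, on the branch leading to the node. Coverage
below 100% records subsequent losses.
"""

import tempfile
from pathlib import Path

from clusterkin import FixtureSpec, generate_bundle
from clusterkin.dollo import (
    count_synapomorphies,
    infer_synapomorphies,
    list_apomorphies,
    node_annotation_summary,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(
        FixtureSpec(n_proteomes=6, seed=7, partial_absence_per_node=1),
        Path(tmp))
    syn = infer_synapomorphies(bundle.tree, bundle.clusters,
                               node_taxon_cov=0.75)
    print("synapomorphic clusters per node (>= 75% taxon coverage):")
    for node, count in count_synapomorphies(syn).items():
        leaves = sorted(bundle.tree.leaves_under[node])
        print(f"  {node} ({','.join(leaves)}): {count}")
        summ = node_annotation_summary(node, syn, bundle.clusters,
                                       bundle.annotations)
        frac = summ["annotated_fraction"]
        print(f"    representative annotation: "
              f"{'N/A' if frac is None else f'{frac:.0%}'}")

    apo = list_apomorphies(bundle.clusters)
    first = bundle.attrs.proteomes[0]
    print(f"\napomorphies of {first}: "
          f"{len(apo[first]['singleton'])} singleton, "
          f"{len(apo[first]['nonsingleton'])} nonsingleton clusters")

# Each cluster maps to at most one node (the MRCA of its members);
# private clusters are apomorphies, not synapomorphies.
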