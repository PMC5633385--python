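# clusterkin

Taxon-aware analysis of clustered protein sequences.

Comparative genomics projects routinely cluster the proteins of many
species into putative gene families (orthogroups) with tools such as
OrthoFinder or OrthoMCL, and then face the harder question: which
clusters are diagnostic for, expanded in, or lost from the groups of
species they care about — clades, hosts, lifestyles, or competing
phylogenetic hypotheses? `clusterkin` answers that question for
user-defined *taxon sets*. It consumes standard clustering outputs
plus a small config table grouping proteomes under arbitrary
attributes, and derives:

- **cluster classification** per attribute — every cluster is typed as
  *singleton* (one protein), *specific* (≥ 2 proteins, all from one
  taxon set) or *shared*, with count/presence matrices and per-level
  summaries;
- **single-copy orthologs** — strict (exactly one protein per
  proteome) and *fuzzy*: a fraction ≥ `target_fraction` of proteomes
  at `target_count` copies, the rest within `[min, max]`;
- **pan-proteome rarefaction curves** — repeated random sampling of a
  set's proteomes, cumulative count of distinct nonsingleton clusters;
- **representation tests** — per-cluster two-sided Mann–Whitney
  *U*-tests (or Welch/Student *t*) comparing per-proteome protein
  counts between two taxon sets, with volcano-plot output of
  log₂-fold change in means vs *P*-value;
- **Dollo-parsimony synapomorphies** — on a supplied Newick topology,
  a cluster is assigned to the node whose descendants alone contain
  its members with every child represented (single gain, unlimited
  losses), classified by taxon coverage into *complete presence*
  (100%) and *partial absence* (≥ `node_taxon_cov`, default 75%);
- **representative functional annotation** — InterProScan-derived
  domain/GO terms promoted to cluster level when they cover at least
  `domain_taxon_cov` of the cluster's proteomes and
  `domain_protein_cov` of its proteins; plus length statistics,
  secretion fractions (SignalP_Euk) and domain/GO term entropy;
- **genes-of-interest reports**, a proteome co-occurrence network
  (GraphML), cluster-size histograms with a reference power-law fit,
  and NCBI-taxonomy rank expansion from TaxIDs.

A deterministic synthetic-bundle generator (`clusterkin.fixtures`)
fabricates complete, internally consistent input sets with a
ground-truth manifest, so every analysis is testable end to end
without any downloads.

## Worked example

The package embeds a three-proteome worked example (proteomes A, B, C
with 5 + 4 + 3 proteins in six clusters):

```python
>>> from clusterkin import toy3_fixture, find_true_scos, cooccurrence_graph
>>> from clusterkin.model import classify_clusters
>>> toy = toy3_fixture()
>>> len(toy.clusters)
6
>>> [r.cluster_type for r in classify_clusters(toy.clusters, toy.attrs, "TAXON")]
['shared', 'shared', 'specific', 'singleton', 'shared', 'singleton']
>>> find_true_scos(toy.clusters)
['OG0', 'OG4']
>>> cooccurrence_graph(toy.clusters)["A"]["B"]["weight"]
3
```

Six clusters: two singletons (OG3, OG5), one A-specific expansion
(OG2), and two universal single-copy clusters (OG0, OG4) that are the
strict single-copy orthologs. A and B co-occur in three clusters —
only one (OG1) once universal clusters are excluded. The scripts in
`examples/` walk through each capability with printed output.

From the shell, the same pipeline runs as:

```bash
clusterkin fixture --toy3 --out toy/
clusterkin analyse -g toy/Orthogroups.txt -s toy/SequenceIDs.txt \
    -c toy/config.csv -f toy/interproscan.tsv -a toy/fasta \
    -t toy/tree.nwk --outgroup C -o out/
```

which writes one subdirectory of TSVs per attribute (`all`, `TAXON`,
`host`), single-copy lists, synapomorphy tables, and plots.

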