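# Methods

## Data model

All analyses operate on a `ClusterCollection` (clusters with
per-proteome protein membership), an `AttributeTable` (each proteome
assigned one level per attribute; the levels of an attribute partition
the proteome list into taxon sets), and optionally an
`AnnotationTable`, a `LengthTable` and a rooted `TreeTopology` whose
leaves are proteome IDs. Two attributes are always injected: `all`
(every proteome in one level) and `TAXON` (each proteome its own
level), so proteome-level results are the special case of the general
taxon-set machinery.

Cluster files may reference proteins by internal `<i>_<j>` tokens
(OrthoFinder working files) or by raw protein IDs (OrthoMCL); the
dialect is auto-detected from the first token. Proteins listed in the
SequenceIDs file but absent from the clustering can optionally be
added as synthetic singletons (`--infer-singletons`, off by default),
since some clustering tools omit unclustered sequences. FASTA headers
are matched on the first whitespace-delimited token, exactly; a
terminal `*` is stripped before length counting. Internal tree nodes
are labelled `n0..nK` in preorder from the root after rooting on the
outgroup split, so published node labels are reproduced only when the
same topology and outgroup are supplied.

## Cluster typing

Under one attribute, a cluster is `singleton` iff it has one protein;
`specific` iff it has ≥ 2 proteins and members from exactly one level;
`shared` otherwise. Note that a two-protein cluster spanning two
proteomes of the same level is *specific* to that level — specificity
is a property of the partition, not of the proteome count. The three
types partition every collection, and protein counts are conserved
across the partition; both facts are enforced by property tests.

## Single-copy orthologs

Strict: exactly one protein from every proteome. Fuzzy: every
proteome's copy number within `[min, max]` and the fraction of
proteomes at exactly `target_count` at least `target_fraction`. With
`min ≥ 1` (the default) every proteome must be present; absence must
be allowed explicitly with `min = 0`. The fraction comparison is done
as an integer cross-multiplication so that boundary cases like 3/4
against a threshold of 0.75 never depend on floating-point rounding of
the ratio. `FuzzyParams(1, 1.0, 1, 1)` reduces exactly to the strict
definition, and relaxing any parameter can only grow the result set —
both are tested, the latter against a brute-force re-evaluation of the
predicate.

## Rarefaction

For each repetition (default 30), the set's proteomes are shuffled
once with a seeded generator and the curve records, at every prefix
size k, the number of distinct nonsingleton clusters having at least
one member among the first k proteomes. Singletons are excluded
throughout, so the final point of every repetition equals the set's
total nonsingleton cluster count — the endpoint is sampling-free. The
repetition count and seed are surfaced as CLI flags.

## Representation tests

For a cluster and two taxon sets, the test vectors are the
per-proteome protein counts over *all* proteomes of each set, zeros
included — absence is the depletion signal. Clusters with no member in
either set are skipped. The default test is the two-sided Mann–Whitney
*U*; up to ~20,000 arrangements (e.g. 8 vs 8) the permutation null is
enumerated exactly, which is also correct under ties, and beyond that
the normal approximation with tie and continuity corrections is used
(verified within 0.02 of full enumeration at n₁ = n₂ = 8). Welch's and
Student's *t*-tests are available as alternatives. The *p*-value is
reported as N/A when either set has fewer than two proteomes (the set
size is the sample size), and as 1.0 when all counts are identical.
Effect size is log₂ of the ratio of means. **Raw p-values are
reported; no multiple-testing correction is applied** — the volcano
plot draws guide lines at raw *P* = 0.05 and 0.01, at |log₂fc| = 1,
and at the 95th percentile (linear interpolation) of |log₂fc| over all
tested clusters.

## Size histogram and co-occurrence network

The cluster-size histogram is broken down by number of contributing
proteomes. The power-law curve `count = C·size^(−γ)` is fitted by
ordinary least squares on log–log axes over nonzero bins; it is a
descriptive reference curve for spotting deviations (such as an excess
at size = number of proteomes), not an inferential estimate. The
co-occurrence graph weights each proteome pair by the number of
clusters containing both; universal clusters (members from every
proteome) can be excluded to expose structure otherwise swamped by the
core proteome. Graphs are written as GraphML.

## Representative annotation and entropy

InterProScan rows are collapsed to unique (protein, namespace, term)
records; all analysis namespaces are passed through verbatim
(Pfam, PRINTS, PANTHER, ...), with `IPR` and `GO` synthesized from
their dedicated columns and `SignalP_Euk` reserved as the secretion
flag. A term is *representative* for a cluster when its proteome
coverage ≥ `domain_taxon_cov` and its protein coverage ≥
`domain_protein_cov`; coverages are exact rationals, and tightening
either threshold can only remove terms. The defaults (0.75, 0.75)
parallel the 75% taxon-coverage convention used for synapomorphy
reporting; there is no community standard, so both are explicit
parameters. Term entropy within a cluster is Shannon entropy in bits
over term-incidence counts (each term weighted by the number of member
proteins carrying it, normalised over all terms of the namespace);
base 2 is fixed and documented since only the quantity's name, not its
formula, is conventional. Length statistics use the sample (n−1) SD,
reported as N/A for singletons to distinguish undefined from zero.

## Dollo synapomorphies

A cluster spanning ≥ 2 proteomes is synapomorphic for the node whose
descendant leaves alone contain its members and whose every child
contributes at least one member — under Dollo parsimony (one gain,
unlimited losses) that is the branch where the family arose. The
implementation assigns the MRCA of the member proteomes and verifies
child support there; the quoted rule itself is retained as the test
oracle, which scans every node on random trees and confirms both
agreement and uniqueness of the satisfying node. Because losses are
unpenalised, records are classified by taxon coverage: complete
presence (= 1), partial absence (≥ `node_taxon_cov`), or below
threshold. Below-threshold records appear in the detailed table but
are excluded from headline counts, keeping the unpenalised Dollo
assignment separate from the 75% reporting convention. Clusters whose
members include proteomes missing from the tree are excluded with a
warning — a tree/config mismatch is a user error, not silently dropped
data. Apomorphies (singleton and nonsingleton proteome-specific
clusters) are listed per proteome and equal the `TAXON`-attribute
singleton/specific classes by construction.

## Synthetic bundles

The generator plants known structure into files written in exactly the
dialects the readers accept: a ladder tree over `n_proteomes`
proteomes; per-node complete-presence synapomorphies (one protein per
descendant leaf) and optional partial-absence ones (one leaf dropped
from the larger child); strict single-copy clusters; fuzzy profiles
with one proteome pushed off target within the configured bounds;
per-proteome singletons; fully annotated Pfam/IPR/GO terms on a
configurable fraction of nonsingleton clusters, SignalP records on
another; sequence lengths drawn from a clipped normal (default mean
350 aa, SD 100 aa, floor 30 aa — typical proteome-scale values); and a
miniature NCBI-style taxdump giving each proteome a
species→genus→order→phylum lineage. Defaults (6 proteomes, 2
synapomorphies per node, 2 singletons per proteome, 4 strict and 3
fuzzy single-copy clusters, 50% annotation coverage) are chosen so
every downstream code path is exercised on a bundle that parses in
milliseconds. All randomness flows from a single seed and files are
written in fixed order, so bundles are byte-identical per seed.

What the generator does **not** emulate: sequence similarity (residues
are uniform random), clustering noise (membership is planted, never
inferred), isoforms, fragmented gene models, or annotation error.
Passing tests therefore demonstrate that the analysis logic recovers
planted truth exactly and that the statistics match independent
enumeration — not that upstream clustering artifacts are handled
gracefully.

## Problem sizes and numerical choices

The test suite runs on bundles of 3–6 proteomes and up to ~170
clusters, with 500 random tree/profile draws for the Dollo oracle and
full permutation enumeration up to C(16,8) arrangements for the
Mann–Whitney cross-check; the acceptance script analyses a 10-proteome,
~300-cluster bundle. These sizes make every check exact or
exhaustively enumerable while completing in seconds. Ties in ranking
representative terms break by protein coverage, then taxon coverage,
then term ID; volcano rows tie-break by cluster ID; percentiles use
linear interpolation. Degenerate inputs (empty namespaces, singleton
SD, single-size histograms, nodes without synapomorphies) are reported
as N/A rather than 0 wherever the value is undefined rather than zero.

## Known limitations

Multiple testing is deliberately uncorrected (documented above).
Isoform filtering of input FASTAs is a preprocessing recommendation,
not implemented. The power-law fit is least squares on log–log axes,
which is known to be biased as an estimator of a true power-law
exponent — acceptable for its reference-curve role only. Remote
retrieval of Pfam/InterPro/GO description mappings is out of scope;
descriptions come from the annotation TSV itself.
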