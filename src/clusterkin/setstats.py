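"""Taxon-set analytics.

* pan-proteome rarefaction curves (repeated random sampling of a set's
  proteomes, cumulative count of distinct nonsingleton clusters)
* pairwise protein-count representation tests between two taxon sets
  (Mann-Whitney U by default; Welch's or Student's t alternatives) with
  volcano-plot output
* cluster-size frequency histogram with a reference power-law fit
* proteome co-occurrence graph (GraphML)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from clusterkin.formats_io import Cluster, ClusterCollection
from clusterkin.model import TaxonSet

TEST_METHODS = ("mwu", "welch", "student")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RarefactionResult:
    taxon_set: TaxonSet
    reps: int
    seed: int
    #: sample size k -> one nonsingleton-cluster count per repetition
    curve: Mapping[int, tuple[int, ...]]

    def means(self) -> dict[int, float]:
        return {k: float(np.mean(v)) for k, v in self.curve.items()}


def rarefaction_curve(clusters: ClusterCollection, taxon_set: TaxonSet,
                      reps: int = 30, seed: int = 0) -> RarefactionResult:
    """Rarefaction of nonsingleton cluster counts within one taxon set.

    For each repetition the set's proteomes are shuffled once; the
    count at sample size k is the number of distinct nonsingleton
    clusters with at least one member among the first k proteomes of
    that permutation. Deterministic for a given seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    members = sorted(taxon_set.proteomes)
    # cluster index -> only nonsingletons with any member in the set
    cluster_proteomes = [c.proteomes & taxon_set.proteomes
                         for c in clusters if c.size > 1]
    cluster_proteomes = [ps for ps in cluster_proteomes if ps]
    by_proteome: dict[str, list[int]] = {p: [] for p in members}
    for idx, ps in enumerate(cluster_proteomes):
        for p in ps:
            by_proteome[p].append(idx)
    rng = np.random.default_rng(seed)
    curve: dict[int, list[int]] = {k: [] for k in range(1, len(members) + 1)}
    for _ in range(reps):
        order = rng.permutation(len(members))
        seen: set[int] = set()
        for k, pos in enumerate(order, 1):
            seen.update(by_proteome[members[pos]])
            curve[k].append(len(seen))
    return RarefactionResult(taxon_set, reps, seed,
                             {k: tuple(v) for k, v in curve.items()})


def write_rarefaction(results: Iterable[RarefactionResult],
                      path: str | Path) -> None:
    """``<attr>.rarefaction.tsv``: one row per (level, k, repetition)."""
    with Path(path).open("w") as fh:
        fh.write("#level\tsample_size\trepetition\tnonsingleton_clusters\n")
        for res in results:
            for k in sorted(res.curve):
                for rep, count in enumerate(res.curve[k]):
                    fh.write(f"{res.taxon_set.level}\t{k}\t{rep}\t{count}\n")


def plot_rarefaction(results: Sequence[RarefactionResult],
                     path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for res in results:
        ks = sorted(res.curve)
        means = [np.mean(res.curve[k]) for k in ks]
        lo = [np.min(res.curve[k]) for k in ks]
        hi = [np.max(res.curve[k]) for k in ks]
        ax.plot(ks, means, marker="o", label=res.taxon_set.level)
        ax.fill_between(ks, lo, hi, alpha=0.2)
    ax.set_xlabel("sampled proteomes")
    ax.set_ylabel("nonsingleton clusters")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# representation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepresentationTestResult:
    cluster_id: str
    set_a: str
    set_b: str
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    mean_a: float
    mean_b: float
    log2fc: float
    pvalue: float | None
    method: str


#: enumerate the permutation null exactly up to this many arrangements
_MWU_EXACT_LIMIT = 20_000


def _mwu_pvalue(a: Sequence[int], b: Sequence[int]) -> float:
    """Two-sided Mann-Whitney U p-value.

    For small samples (up to ~C(16,8) arrangements) the permutation
    null is enumerated exactly, which handles ties correctly; larger
    samples use the normal approximation with tie correction and
    continuity correction.
    """
    n1, n2 = len(a), len(b)
    if math.comb(n1 + n2, min(n1, n2)) <= _MWU_EXACT_LIMIT:
        method = stats.PermutationMethod(n_resamples=_MWU_EXACT_LIMIT)
    else:
        method = "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method=method, use_continuity=True)
    return float(res.pvalue)


def representation_test(cluster: Cluster, set_a: TaxonSet, set_b: TaxonSet,
                        method: str = "mwu") -> RepresentationTestResult | None:
    """Protein-count representation test for one cluster between two sets.

    The count vectors span *all* proteomes of each set, zeros included
    (absence from the cluster is the depletion signal). Clusters lacking
    members from either set entirely are skipped (returns ``None``).
    The p-value is N/A when either set has fewer than two proteomes;
    identical constant counts on both sides give p = 1.0 by convention.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown test method {method!r}; "
                         f"choose from {TEST_METHODS}")
    counts_a = tuple(cluster.count(p) for p in sorted(set_a.proteomes))
    counts_b = tuple(cluster.count(p) for p in sorted(set_b.proteomes))
    if sum(counts_a) == 0 or sum(counts_b) == 0:
        return None
    mean_a = sum(counts_a) / len(counts_a)
    mean_b = sum(counts_b) / len(counts_b)
    log2fc = math.log2(mean_a / mean_b)
    pvalue: float | None
    if len(counts_a) < 2 or len(counts_b) < 2:
        pvalue = None
    elif len(set(counts_a + counts_b)) == 1:
        pvalue = 1.0
    elif method == "mwu":
        pvalue = _mwu_pvalue(counts_a, counts_b)
    else:
        equal_var = method == "student"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(counts_a, counts_b, equal_var=equal_var)
        pvalue = float(res.pvalue)
        if math.isnan(pvalue):
            pvalue = 1.0
    return RepresentationTestResult(cluster.cluster_id, set_a.level,
                                    set_b.level, counts_a, counts_b,
                                    mean_a, mean_b, log2fc, pvalue, method)


def representation_tests(clusters: ClusterCollection, set_a: TaxonSet,
                         set_b: TaxonSet, method: str = "mwu",
                         ) -> list[RepresentationTestResult]:
    """Run the representation test over every eligible cluster."""
    out = []
    for c in clusters:
        res = representation_test(c, set_a, set_b, method)
        if res is not None:
            out.append(res)
    return out


def volcano_table(results: Sequence[RepresentationTestResult],
                  tsv_path: str | Path | None = None,
                  plot_path: str | Path | None = None) -> list[
                      RepresentationTestResult]:
    """Sort results by p-value; optionally write TSV and volcano plot.

    The plot draws horizontal guide lines at p = 0.05 and 0.01 and
    vertical lines at |log2 fold change| = 1 and at the 95th percentile
    (linear interpolation) of |log2fc| over all tested clusters. Raw
    p-values are reported; no multiple-testing correction is applied.
    """
    if not results:
        raise ValueError("no representation test results to report")
    ordered = sorted(results,
                     key=lambda r: (r.pvalue is None,
                                    r.pvalue if r.pvalue is not None else 0.0,
                                    r.cluster_id))
    if tsv_path is not None:
        with Path(tsv_path).open("w") as fh:
            fh.write("#cluster_id\tset_a\tset_b\tmean_a\tmean_b\t"
                     "log2fc\tpvalue\tmethod\tcounts_a\tcounts_b\n")
            for r in ordered:
                pv = "N/A" if r.pvalue is None else f"{r.pvalue:.6g}"
                fh.write(f"{r.cluster_id}\t{r.set_a}\t{r.set_b}\t"
                         f"{r.mean_a:.6g}\t{r.mean_b:.6g}\t{r.log2fc:.6g}\t"
                         f"{pv}\t{r.method}\t"
                         f"{','.join(map(str, r.counts_a))}\t"
                         f"{','.join(map(str, r.counts_b))}\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tested = [r for r in ordered if r.pvalue is not None]
        fcs = np.array([r.log2fc for r in tested])
        pvs = np.array([max(r.pvalue, 1e-300) for r in tested])
        pct95 = float(np.percentile(np.abs(fcs), 95)) if len(fcs) else 0.0
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(fcs, -np.log10(pvs), s=12, alpha=0.6)
        for p in (0.05, 0.01):
            ax.axhline(-math.log10(p), color="gray", ls="--", lw=0.8)
        for x in (-1.0, 1.0):
            ax.axvline(x, color="gray", ls="--", lw=0.8)
        for x in (-pct95, pct95):
            ax.axvline(x, color="firebrick", ls=":", lw=0.8)
        ax.set_xlabel("log2 fold change of mean counts")
        ax.set_ylabel("-log10 p-value")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return ordered


def log2fc_percentile(results: Sequence[RepresentationTestResult],
                      q: float = 95.0) -> float:
    """Percentile (linear interpolation) of |log2fc| over tested clusters."""
    vals = [abs(r.log2fc) for r in results if r.pvalue is not None]
    if not vals:
        raise ValueError("no tested clusters")
    return float(np.percentile(vals, q))


# ---------------------------------------------------------------------------
# cluster size distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeHistogram:
    #: cluster size -> total cluster count
    counts: Mapping[int, int]
    #: cluster size -> {number of contributing proteomes -> cluster count}
    by_proteome_count: Mapping[int, Mapping[int, int]]
    #: least-squares fit of count = C * size^(-gamma) on log-log axes,
    #: or None when fewer than two distinct sizes are observed
    powerlaw: tuple[float, float] | None

    @property
    def gamma(self) -> float | None:
        return self.powerlaw[1] if self.powerlaw else None


def size_histogram_and_powerlaw(
        clusters: ClusterCollection | Mapping[int, int]) -> SizeHistogram:
    """Cluster-size histogram with a reference power-law fit.

    The fit is a simple least-squares line on (log size, log count)
    over nonzero bins — a descriptive reference curve, not an
    inferential estimate. Accepts a collection or a precomputed
    ``{size: count}`` histogram.
    """
    by_pc: dict[int, dict[int, int]] = {}
    if isinstance(clusters, ClusterCollection):
        counts: dict[int, int] = {}
        for c in clusters:
            counts[c.size] = counts.get(c.size, 0) + 1
            per = by_pc.setdefault(c.size, {})
            per[c.proteome_count] = per.get(c.proteome_count, 0) + 1
    else:
        counts = dict(clusters)
    counts = dict(sorted(counts.items()))
    powerlaw: tuple[float, float] | None = None
    nonzero = [(s, n) for s, n in counts.items() if n > 0]
    if len(nonzero) >= 2:
        xs = np.log([s for s, _ in nonzero])
        ys = np.log([n for _, n in nonzero])
        slope, intercept = np.polyfit(xs, ys, 1)
        powerlaw = (float(np.exp(intercept)), float(-slope))
    return SizeHistogram(counts, {s: dict(d) for s, d in by_pc.items()},
                         powerlaw)


def write_size_histogram(hist: SizeHistogram, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#cluster_size\tcluster_count\tby_proteome_count\n")
        for s, n in hist.counts.items():
            breakdown = ";".join(
                f"{pc}:{cnt}" for pc, cnt
                in sorted(hist.by_proteome_count.get(s, {}).items()))
            fh.write(f"{s}\t{n}\t{breakdown}\n")


def plot_size_histogram(hist: SizeHistogram, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sizes = sorted(hist.counts)
    ax.scatter(sizes, [hist.counts[s] for s in sizes], s=14, color="gray")
    if hist.powerlaw:
        C, gamma = hist.powerlaw
        xs = np.linspace(min(sizes), max(sizes), 200)
        ax.plot(xs, C * xs ** (-gamma), color="gray", lw=1,
                label=f"power law, gamma={gamma:.2f}")
        ax.legend(fontsize="small")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("cluster size (proteins)")
    ax.set_ylabel("clusters")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# co-occurrence graph
# ---------------------------------------------------------------------------

def cooccurrence_graph(clusters: ClusterCollection,
                       exclude_universal: bool = False) -> nx.Graph:
    """Proteome co-occurrence network.

    Nodes are proteomes; the weight of edge (u, v) is the number of
    clusters containing at least one protein of each. Universal
    clusters (members from every proteome) can be excluded to expose
    structure otherwise swamped by the core proteome.
    """
    n_total = len(clusters.proteome_ids)
    g = nx.Graph()
    g.add_nodes_from(clusters.proteome_ids)
    for c in clusters:
        ps = sorted(c.proteomes)
        if len(ps) < 2:
            continue
        if exclude_universal and len(ps) == n_total:
            continue
        for i, u in enumerate(ps):
            for v in ps[i + 1:]:
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1)
    return g


def write_cooccurrence_graph(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
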