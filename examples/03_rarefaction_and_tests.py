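"""Pan-proteome rarefaction and protein-count representation tests.

Rarefaction shows how many distinct nonsingleton clusters are recovered
as proteomes of a set are sampled cumulatively; the representation test
asks, cluster by cluster, whether protein counts differ between two
taxon sets (two-sided Mann-Whitney U by default).
"""

import tempfile
from pathlib import Path

from clusterkin import FixtureSpec, generate_bundle
from clusterkin.model import taxon_sets
from clusterkin.setstats import rarefaction_curve, representation_tests

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_bundle(FixtureSpec(n_proteomes=8, seed=11), Path(tmp))
    by_level = {s.level: s for s in taxon_sets(bundle.attrs, "habitat")}
    host, free = by_level["host"], by_level["free"]
    res = rarefaction_curve(bundle.clusters, host, reps=30, seed=1)
    print(f"rarefaction of set {host.level!r} ({len(host)} proteomes), "
          "mean nonsingleton clusters:")
    for k, mean in res.means().items():
        print(f"  {k} proteomes sampled -> {mean:.1f}")

    tests = representation_tests(bundle.clusters, host, free)
    tested = [t for t in tests if t.pvalue is not None]
    tested.sort(key=lambda t: t.pvalue)
    print(f"\n{len(tests)} clusters tested {host.level} vs {free.level}; "
          "most extreme:")
    for t in tested[:5]:
        print(f"  {t.cluster_id}: log2fc={t.log2fc:+.2f} p={t.pvalue:.3f}")

# The curve's final point equals the set's total nonsingleton cluster
# count; a negative log2fc marks clusters depleted in the first set.
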