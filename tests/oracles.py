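"""Independent brute-force oracles used only by the tests.

These deliberately re-derive each quantity from first principles
(enumeration, direct rule application) without touching the library's
implementation paths, so a test comparing the two routes is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence


def mwu_exact_two_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value by full permutation enumeration.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes, computes U for each (ties counted 1/2), and returns
    the fraction of assignments at least as far from the null mean
    n1*n2/2 as the observed U.
    """
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a: Sequence[float], group_b: Sequence[float]) -> float:
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    center = n1 * (len(pooled) - n1) / 2.0
    dev_obs = abs(u_obs - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(ga, gb) - center) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def fuzzy_sco_predicate(counts: dict[str, int], proteomes: Sequence[str],
                        target_count: int, target_fraction: float,
                        lo: int, hi: int) -> bool:
    """Direct restatement of the fuzzy single-copy rule."""
    full = [counts.get(p, 0) for p in proteomes]
    if any(c < lo or c > hi for c in full):
        return False
    n_at = sum(1 for c in full if c == target_count)
    return n_at / len(proteomes) >= target_fraction - 1e-12


def dollo_nodes_by_search(tree, member_proteomes: frozenset[str]) -> list[str]:
    """All internal nodes satisfying the synapomorphy rule, by scanning
    every node: members within the node's leaves and every child of the
    node contributing at least one member."""
    out = []
    for node in tree.internal_nodes:
        if not member_proteomes <= tree.leaves_under[node]:
            continue
        if all(member_proteomes & tree.leaves_under[c]
               for c in tree.children[node]):
            out.append(node)
    return out
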