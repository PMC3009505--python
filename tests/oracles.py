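"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the package's enumeration and alignment code:
q-grams are found by exhaustive node-subset search, and alignments by
exhaustive search over structure-preserving node mappings.
"""

from __future__ import annotations

import itertools
from collections import Counter

from glyqgram.core import Glycan


def brute_qgrams(g: Glycan, q: int, *, straight_only: bool = False) -> Counter:
    """All q-gram occurrences by exhaustive subset enumeration.

    Returns a multiset of canonical tuples ``(shape, monos, bonds,
    layer)``: every q-node subset is tested for connectivity and
    internal degree <= 2, then canonicalized from its apex (unique
    minimum-layer node) with arms ordered by (length desc, mono
    sequence, bond sequence).
    """
    nodes = sorted(g.monos)
    lay = g.layers()
    parent = {c: p for c, (p, _) in g.parents.items()}
    bond = {c: b for c, (_, b) in g.parents.items()}
    found: Counter = Counter()
    for subset in itertools.combinations(nodes, q):
        sset = set(subset)
        adj = {u: [] for u in subset}
        for c in subset:
            p = parent.get(c)
            if p in sset:
                adj[c].append(p)
                adj[p].append(c)
        if any(len(v) > 2 for v in adj.values()):
            continue
        seen = {subset[0]}
        stack = [subset[0]]
        while stack:
            for v in adj[stack.pop()]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != q:
            continue
        apex = min(subset, key=lambda u: lay[u])
        arms = []
        for k in sorted(c for c in subset if parent.get(c) == apex):
            chain_nodes, chain_bonds = [], []
            cur = k
            while True:
                chain_nodes.append(cur)
                chain_bonds.append(bond[cur])
                below = [c for c in subset if parent.get(c) == cur]
                if not below:
                    break
                cur = below[0]  # degree <= 2: at most one continuation
            arms.append(
                (
                    tuple(g.monos[v] for v in chain_nodes),
                    tuple(chain_bonds),
                )
            )
        if straight_only and len(arms) > 1:
            continue
        arms.sort(key=lambda a: (-len(a[0]), a[0], a[1]))
        if len(arms) == 1:
            shape = (q, 0)
            monos = (g.monos[apex],) + arms[0][0]
            bonds = arms[0][1]
        elif len(arms) == 2:
            shape = (1 + len(arms[0][0]), len(arms[1][0]))
            monos = (g.monos[apex],) + arms[0][0] + arms[1][0]
            bonds = arms[0][1] + arms[1][1]
        else:  # q == 1
            shape, monos, bonds = (1, 0), (g.monos[apex],), ()
        found[(shape, monos, bonds, lay[apex])] += 1
    return found


def qgram_tuples(occurrences) -> Counter:
    """Package q-gram occurrences as the oracle's tuple multiset."""
    return Counter((o.shape, o.monos, o.bonds, o.layer) for o in occurrences)


def brute_align(s: Glycan, t: Glycan, w) -> float:
    """Best structure-preserving mapping score by exhaustive search.

    Enumerates every injective node mapping that preserves the ancestor
    relation in both directions and keeps disjoint child subtrees
    disjoint (the lca-consistency condition), and returns the maximum
    total node score.  Only meaningful for tiny trees.
    """
    s_nodes = sorted(s.monos)
    t_nodes = sorted(t.monos)
    anc_s, lca_s = _ancestor_tables(s)
    anc_t, lca_t = _ancestor_tables(t)

    best = 0.0
    for k in range(1, min(len(s_nodes), len(t_nodes)) + 1):
        for s_sub in itertools.combinations(s_nodes, k):
            for t_perm in itertools.permutations(t_nodes, k):
                mapping = tuple(zip(s_sub, t_perm))
                if _valid_mapping(mapping, anc_s, anc_t, lca_s, lca_t):
                    score = sum(w(u, v) for u, v in mapping)
                    best = max(best, score)
    return best


def _ancestor_tables(g: Glycan):
    """Strict-ancestor sets and an all-pairs lowest-common-ancestor table."""
    anc: dict[int, set[int]] = {}
    chain: dict[int, list[int]] = {}
    for u in g.preorder():
        if u == g.root:
            chain[u] = [u]
        else:
            chain[u] = chain[g.parents[u][0]] + [u]
        anc[u] = set(chain[u][:-1])
    lca: dict[tuple[int, int], int] = {}
    for u in g.monos:
        for v in g.monos:
            common = [x for x in chain[u] if x in set(chain[v])]
            lca[(u, v)] = common[-1]
    return anc, lca


def _valid_mapping(mapping, anc_s, anc_t, lca_s, lca_t) -> bool:
    for (u1, v1), (u2, v2) in itertools.combinations(mapping, 2):
        if (u1 in anc_s[u2]) != (v1 in anc_t[v2]):
            return False
        if (u2 in anc_s[u1]) != (v2 in anc_t[v1]):
            return False
    # lca consistency: child subtrees that are disjoint on one side must
    # stay disjoint on the other (ordered triples)
    for (u1, v1), (u2, v2), (u3, v3) in itertools.permutations(mapping, 3):
        lu = lca_s[(u1, u2)]
        lv = lca_t[(v1, v2)]
        if (lu in anc_s[u3] or lu == u3) != (lv in anc_t[v3] or lv == v3):
            return False
    return True
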