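"""KCaM-style dynamic-programming tree alignment for glycans.

The aligner follows the approximate-matching recursion used by the KEGG
Carbohydrate Matcher family of algorithms: for a node pair ``(u, v)``

    Q[u][v] = max( w(u, v) + best children assignment Σ Q[c_u][c_v],
                   max over children c_u of  Q[c_u][v] - gap,
                   max over children c_v of  Q[u][c_v] - gap,
                   0 )

where the children assignment is an injective matching between the two
child lists, solved exactly by exhaustion (glycan nodes have at most
four children, so at most 4! injections).  The resulting mapping pairs
nodes so that ancestry and subtree-disjointness are preserved on both
sides; skips are free at the default gap penalty of 0.

Two node-scoring rules are provided:

* ``exact`` (KM): ``w(u, v) = 1`` iff the monosaccharide labels are
  equal and the bonds to the parents are equal (the root's wildcard
  bond matches anything); structure similarity only.
* ``linkage`` (LKM): ``w(u, v)`` is the product of monosaccharide,
  bond, and layer similarities, crediting chemically similar but
  non-identical components.

Raw scores are normalized to 0-100 by the geometric mean of the two
self-alignment scores, so a structure scores exactly 100 against itself
and scores are symmetric.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import WILDCARD_BOND, Glycan, GlycanError
from .qgrams import QGram, QGramIndex
from .similarity import LinkageTables, SimilarityMatrix, layer_similarity


@dataclass
class AlignParams:
    """Alignment configuration.

    ``mode='global'`` reads the score at the root pair (with free skips
    descending either side); ``mode='local'`` takes the best score over
    all node pairs.  ``node_score`` selects exact-match (KM) or
    linkage-weighted (LKM) scoring; the latter uses ``tables``.
    """

    mode: str = "global"
    node_score: str = "exact"
    gap_penalty: float = 0.0
    tables: LinkageTables = field(default_factory=LinkageTables.default)

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise GlycanError(f"unknown alignment mode {self.mode!r}")
        if self.node_score not in ("exact", "linkage"):
            raise GlycanError(f"unknown node score rule {self.node_score!r}")
        if self.gap_penalty < 0:
            raise GlycanError("gap penalty must be >= 0")


@dataclass
class AlignResult:
    raw_score: float
    normalized: float
    pairs: list[tuple[int, int]]


class _Aligner:
    def __init__(
        self,
        s: Glycan,
        t: Glycan,
        params: AlignParams,
        base_layer_s: int = 0,
        base_layer_t: int = 0,
    ) -> None:
        self.s, self.t, self.p = s, t, params
        self.lay_s = {u: l + base_layer_s for u, l in s.layers().items()}
        self.lay_t = {v: l + base_layer_t for v, l in t.layers().items()}
        self.memo: dict[tuple[int, int], float] = {}

    def node_score(self, u: int, v: int) -> float:
        ms, mt = self.s.monos[u], self.t.monos[v]
        bs, bt = self.s.parent_bond(u), self.t.parent_bond(v)
        if self.p.node_score == "exact":
            bond_ok = bs == bt or WILDCARD_BOND in (bs, bt)
            return 1.0 if (ms == mt and bond_ok) else 0.0
        tab = self.p.tables
        return (
            tab.mono.score(ms, mt)
            * tab.bond.score(bs, bt)
            * layer_similarity(
                self.lay_s[u], self.lay_t[v], formula=tab.layer_formula
            )
        )

    def q(self, u: int, v: int) -> float:
        key = (u, v)
        if key in self.memo:
            return self.memo[key]
        self.memo[key] = 0.0  # placeholder; trees are acyclic so unused
        best = self.node_score(u, v) + self._best_assignment(u, v)
        gap = self.p.gap_penalty
        for cu, _ in self.s.children(u):
            best = max(best, self.q(cu, v) - gap)
        for cv, _ in self.t.children(v):
            best = max(best, self.q(u, cv) - gap)
        best = max(best, 0.0)  # the empty alignment of the two subtrees
        self.memo[key] = best
        return best

    def _best_assignment(self, u: int, v: int) -> float:
        a = [c for c, _ in self.s.children(u)]
        b = [c for c, _ in self.t.children(v)]
        if not a or not b:
            return 0.0
        if len(a) > len(b):
            return max(
                sum(self.q(x, y) for x, y in zip(perm, b))
                for perm in itertools.permutations(a, len(b))
            )
        return max(
            sum(self.q(x, y) for x, y in zip(a, perm))
            for perm in itertools.permutations(b, len(a))
        )

    def raw(self) -> tuple[float, tuple[int, int]]:
        if self.p.mode == "global":
            pair = (self.s.root, self.t.root)
            return self.q(*pair), pair
        best, pair = 0.0, (self.s.root, self.t.root)
        for u in self.s.preorder():
            for v in self.t.preorder():
                val = self.q(u, v)
                if val > best:
                    best, pair = val, (u, v)
        return best, pair

    def traceback(self, u: int, v: int) -> list[tuple[int, int]]:
        val = self.q(u, v)
        if val <= 0.0:
            return []
        gap = self.p.gap_penalty
        match_val = self.node_score(u, v) + self._best_assignment(u, v)
        if math.isclose(val, match_val, rel_tol=0, abs_tol=1e-12):
            pairs = [(u, v)] if self.node_score(u, v) > 0 else []
            pairs.extend(self._traceback_assignment(u, v))
            return pairs
        for cu, _ in self.s.children(u):
            if math.isclose(val, self.q(cu, v) - gap, abs_tol=1e-12):
                return self.traceback(cu, v)
        for cv, _ in self.t.children(v):
            if math.isclose(val, self.q(u, cv) - gap, abs_tol=1e-12):
                return self.traceback(u, cv)
        return []

    def _traceback_assignment(self, u: int, v: int) -> list[tuple[int, int]]:
        a = [c for c, _ in self.s.children(u)]
        b = [c for c, _ in self.t.children(v)]
        if not a or not b:
            return []
        best_sum, best_match = -1.0, []
        small, big, flip = (a, b, False) if len(a) <= len(b) else (b, a, True)
        for perm in itertools.permutations(big, len(small)):
            total = sum(
                self.q(y, x) if flip else self.q(x, y)
                for x, y in zip(small, perm)
            )
            if total > best_sum:
                best_sum = total
                best_match = [
                    (y, x) if flip else (x, y) for x, y in zip(small, perm)
                ]
        out: list[tuple[int, int]] = []
        for x, y in best_match:
            out.extend(self.traceback(x, y))
        return out


def kcam_align(
    s: Glycan,
    t: Glycan,
    params: AlignParams | None = None,
    *,
    base_layer_s: int = 0,
    base_layer_t: int = 0,
) -> AlignResult:
    """Align two glycans; returns raw score, 0-100 score, aligned pairs."""
    if params is None:
        params = AlignParams()
    if s.n_nodes == 0 or t.n_nodes == 0:
        raise GlycanError("cannot align an empty glycan")
    aligner = _Aligner(s, t, params, base_layer_s, base_layer_t)
    raw, pair = aligner.raw()
    self_s, _ = _Aligner(s, s, params, base_layer_s, base_layer_s).raw()
    self_t, _ = _Aligner(t, t, params, base_layer_t, base_layer_t).raw()
    if self_s <= 0 or self_t <= 0:
        raise GlycanError(
            "self-alignment score is 0; node scoring must give every node a "
            "positive self score"
        )
    normalized = 100.0 * raw / math.sqrt(self_s * self_t)
    normalized = min(100.0, max(0.0, normalized))
    return AlignResult(raw, normalized, aligner.traceback(*pair))


def kcam_score(
    s: Glycan,
    t: Glycan,
    params: AlignParams | None = None,
    *,
    base_layer_s: int = 0,
    base_layer_t: int = 0,
) -> float:
    """Normalized KCaM similarity in [0, 100]; 100 on self-alignment."""
    return kcam_align(
        s, t, params, base_layer_s=base_layer_s, base_layer_t=base_layer_t
    ).normalized


def qgram_as_glycan(qg: QGram, id: str | None = None) -> Glycan:
    """Materialize a q-gram as a small glycan tree (apex as root)."""
    monos = {i + 1: m for i, m in enumerate(qg.monos)}
    parents: dict[int, tuple[int, str]] = {}
    len1, len2 = qg.shape
    # first chain: apex (node 1) then nodes 2..len1 descending
    for i in range(2, len1 + 1):
        parents[i] = (i - 1, qg.bonds[i - 2])
    # second chain attaches to the apex
    for k in range(len2):
        node = len1 + 1 + k
        parent = 1 if k == 0 else node - 1
        parents[node] = (parent, qg.bonds[len1 - 1 + k])
    return Glycan(id or qg.key, monos, parents)


def _pairwise_matrix(
    index: QGramIndex, params: AlignParams, use_layers: bool
) -> np.ndarray:
    reps = index.representatives()
    trees = [qgram_as_glycan(e) for e in reps]
    bases = [e.layer if use_layers else 0 for e in reps]
    d = len(trees)
    values = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            score = kcam_score(
                trees[i],
                trees[j],
                params,
                base_layer_s=bases[i],
                base_layer_t=bases[j],
            )
            values[i, j] = values[j, i] = score / 100.0
    return values


def km_matrix(index: QGramIndex, params: AlignParams | None = None) -> SimilarityMatrix:
    """KCaM (KM) inter-q-gram similarity: exact-match structure alignment.

    Normalized scores are rescaled from 0-100 to [0, 1] for kernel use;
    the diagonal is exactly 1.
    """
    if params is None:
        params = AlignParams(node_score="exact")
    return SimilarityMatrix(index.q, index.keys, _pairwise_matrix(index, params, False), "KM")


def lkm_matrix(
    index: QGramIndex, params: AlignParams | None = None
) -> SimilarityMatrix:
    """Linkage-KCaM (LKM) similarity: alignment with linkage-weighted scores.

    Node scores incorporate monosaccharide, bond and layer similarity;
    each q-gram's apex sits at its corpus-representative layer so layer
    context survives materialization.
    """
    if params is None:
        params = AlignParams(node_score="linkage")
    elif params.node_score != "linkage":
        raise GlycanError("lkm_matrix requires linkage-weighted node scoring")
    return SimilarityMatrix(index.q, index.keys, _pairwise_matrix(index, params, True), "LKM")
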