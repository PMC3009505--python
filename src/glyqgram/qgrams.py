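"""q-gram enumeration, canonicalization, indexing and count matrices.

A *q-gram* of a glycan is a connected subtree with ``q`` nodes in which
every node has at most two neighbors inside the subtree — i.e. a path
drawn on the tree.  Because the tree is rooted, such a path either runs
straight down an ancestor→descendant line, or bends at a unique *apex*
(its shallowest node) and descends through two distinct children.  The
shape descriptor ``σ = (len_first, len_second)`` records how the path
splits at the apex: ``(q, 0)`` for a straight chain, ``(1+a, b)`` for a
bent path whose apex carries arms of ``a`` and ``b`` nodes.

Canonical form: traversal starts at the apex and walks the first chain
top-down, then the second chain top-down.  For bent paths the two arms
are ordered by (length descending, then mono-label sequence, then
bond-label sequence), which makes the encoding deterministic and
embedding-invariant.  The identity key of a q-gram is ``(q, σ, monos,
bonds)``; the layer of the apex is carried alongside each occurrence
but deliberately excluded from the key, so identical substructures at
different depths count as the same feature — layers enter only the
similarity computations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Glycan, GlycanError


@dataclass(frozen=True)
class QGram:
    """A canonicalized q-gram occurrence.

    ``monos`` lists the apex first, then the first chain's remaining
    nodes top-down, then the second chain top-down; ``bonds`` lists the
    ``q - 1`` bonds in the same traversal order (the bond joining the
    apex to each arm comes first within that arm's segment).
    """

    q: int
    shape: tuple[int, int]
    monos: tuple[str, ...]
    bonds: tuple[str, ...]
    layer: int

    def __post_init__(self) -> None:
        if len(self.monos) != self.q or len(self.bonds) != self.q - 1:
            raise GlycanError(
                f"q-gram with q={self.q} needs {self.q} monos and "
                f"{self.q - 1} bonds"
            )

    @property
    def key(self) -> str:
        """Canonical identity key; excludes the layer."""
        return "|".join(
            [
                str(self.q),
                f"{self.shape[0]}.{self.shape[1]}",
                *self.monos,
                *self.bonds,
            ]
        )


def _down_chains(
    g: Glycan, u: int, length: int
) -> list[tuple[tuple[int, ...], tuple[str, ...]]]:
    """All downward chains of ``length`` nodes starting at ``u``."""
    if length == 1:
        return [((u,), ())]
    out = []
    for c, bond in g.children(u):
        for nodes, bonds in _down_chains(g, c, length - 1):
            out.append(((u,) + nodes, (bond,) + bonds))
    return out


def enumerate_qgrams(
    g: Glycan, q: int, *, straight_only: bool = False
) -> list[QGram]:
    """Enumerate every q-gram embedding of ``g``, canonicalized.

    One :class:`QGram` is returned per embedding (a multiset: repeated
    substructures appear once per occurrence).  ``straight_only``
    restricts enumeration to straight ancestor→descendant chains,
    dropping bent paths.
    """
    if q < 1:
        raise GlycanError(f"q must be >= 1, got {q}")
    lay = g.layers()
    occ: list[QGram] = []
    for u in g.preorder():
        for nodes, bonds in _down_chains(g, u, q):
            occ.append(
                QGram(
                    q,
                    (q, 0),
                    tuple(g.monos[v] for v in nodes),
                    bonds,
                    lay[u],
                )
            )
        if q >= 3 and not straight_only:
            kids = g.children(u)
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a in range(1, q - 1):
                        b = q - 1 - a
                        arms1 = _down_chains(g, kids[i][0], a)
                        if not arms1:
                            continue
                        arms2 = _down_chains(g, kids[j][0], b)
                        for n1, b1 in arms1:
                            for n2, b2 in arms2:
                                occ.append(
                                    _bent_qgram(
                                        g,
                                        u,
                                        (n1, (kids[i][1],) + b1),
                                        (n2, (kids[j][1],) + b2),
                                        lay[u],
                                        q,
                                    )
                                )
    return occ


def _bent_qgram(g, apex, arm_a, arm_b, layer, q) -> QGram:
    def arm_key(arm):
        nodes, bonds = arm
        return (-len(nodes), tuple(g.monos[v] for v in nodes), bonds)

    first, second = sorted((arm_a, arm_b), key=arm_key)
    monos = (
        (g.monos[apex],)
        + tuple(g.monos[v] for v in first[0])
        + tuple(g.monos[v] for v in second[0])
    )
    bonds = first[1] + second[1]
    return QGram(q, (1 + len(first[0]), len(second[0])), monos, bonds, layer)


class QGramIndex:
    """Ordered unique q-gram vocabulary over a glycan corpus.

    Entries are representative :class:`QGram` objects in first-seen
    order; ``d_q`` is the vocabulary size.  Layer statistics per key are
    retained so that similarity computations can assign each key its
    corpus-representative layer (the most frequent layer, ties broken
    toward the root).
    """

    def __init__(self, q: int) -> None:
        self.q = q
        self.entries: list[QGram] = []
        self.key_to_pos: dict[str, int] = {}
        self.layer_counts: dict[str, Counter] = {}

    @property
    def d_q(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> list[str]:
        return [e.key for e in self.entries]

    def add(self, qg: QGram) -> int:
        key = qg.key
        pos = self.key_to_pos.get(key)
        if pos is None:
            pos = len(self.entries)
            self.entries.append(qg)
            self.key_to_pos[key] = pos
            self.layer_counts[key] = Counter()
        self.layer_counts[key][qg.layer] += 1
        return pos

    def representative_layers(self) -> dict[str, int]:
        """Most frequent layer per key; ties go to the smallest layer."""
        out = {}
        for key, counts in self.layer_counts.items():
            best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            out[key] = best[0]
        return out

    def representatives(self) -> list[QGram]:
        """Entries with the layer replaced by the corpus representative."""
        rep = self.representative_layers()
        return [replace(e, layer=rep[e.key]) for e in self.entries]

    def to_tsv(self) -> str:
        rep = self.representative_layers()
        lines = ["key\tlayer"]
        lines += [f"{e.key}\t{rep[e.key]}" for e in self.entries]
        return "\n".join(lines) + "\n"


def build_index(
    glycans: Iterable[Glycan], q: int, *, straight_only: bool = False
) -> QGramIndex:
    """Index the union of canonical q-gram keys over ``glycans``."""
    index = QGramIndex(q)
    for g in glycans:
        for qg in enumerate_qgrams(g, q, straight_only=straight_only):
            index.add(qg)
    return index


@dataclass
class CountMatrix:
    """``d_q × n`` table of q-gram occurrence counts.

    Column ``s`` is the q-gram representation of glycan ``s``: entry
    ``(i, s)`` counts the embeddings of the i-th indexed q-gram in that
    glycan.
    """

    q: int
    keys: list[str]
    glycan_ids: list[str]
    values: np.ndarray  # int, d_q x n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.keys, columns=self.glycan_ids)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="key")

    @classmethod
    def from_tsv(cls, text: str, q: int) -> "CountMatrix":
        df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", index_col=0)
        return cls(q, list(df.index), list(df.columns), df.to_numpy(dtype=np.int64))


def count_matrix(
    glycans: Sequence[Glycan],
    index: QGramIndex,
    *,
    policy: str = "strict",
    straight_only: bool = False,
) -> CountMatrix:
    """Build the count matrix of ``glycans`` over ``index``.

    ``policy='strict'`` raises on a q-gram key absent from the index
    (guards against silent feature-space leakage between train and test
    corpora); ``policy='extend'`` appends unseen keys to the index in
    place.
    """
    if policy not in ("strict", "extend"):
        raise GlycanError(f"unknown unseen-key policy {policy!r}")
    per_glycan: list[Counter] = []
    for g in glycans:
        counts: Counter = Counter()
        for qg in enumerate_qgrams(g, index.q, straight_only=straight_only):
            if qg.key not in index.key_to_pos:
                if policy == "strict":
                    raise GlycanError(
                        f"glycan {g.id}: q-gram key {qg.key!r} not in index "
                        "(policy=strict)"
                    )
                index.add(qg)
            counts[qg.key] += 1
        per_glycan.append(counts)
    values = np.zeros((index.d_q, len(per_glycan)), dtype=np.int64)
    for s, counts in enumerate(per_glycan):
        for key, c in counts.items():
            values[index.key_to_pos[key], s] = c
    return CountMatrix(index.q, index.keys, [g.id for g in glycans], values)
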