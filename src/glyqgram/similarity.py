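"""Linkage (LK) similarity between q-grams.

Two q-grams of the same ``q`` are comparable only if their structure
shapes agree; q-grams with different shapes are treated as totally
different (similarity 0).  For same-shape q-grams the similarity
combines three components under the canonical position alignment:

* layer similarity between the two apex layers,
* monosaccharide similarity at each matched position,
* glycosidic bond similarity at each matched position.

The default combination rule is the product, so any component that is
completely dissimilar annihilates the match; a mean rule is available
behind a switch.  Bond similarities ship as a 15x15 table over the most
frequent glycosidic bonds (symmetrized, unit diagonal); monosaccharide
similarity defaults to identity and can be replaced by a user-supplied
table (e.g. scores derived from the SIMCOMP chemical-structure
comparison method).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .core import WILDCARD_BOND, GlycanError
from .qgrams import QGram, QGramIndex


class _PairTable:
    """Symmetric label-pair score table with [0,1] range."""

    def __init__(self, scores: dict[tuple[str, str], float], labels: list[str]):
        self.labels = labels
        self._scores: dict[tuple[str, str], float] = {}
        for (a, b), v in scores.items():
            if not 0.0 <= v <= 1.0:
                raise GlycanError(f"similarity {a},{b}={v} outside [0,1]")
            self._scores[self._pair(a, b)] = v
        for lab in labels:
            self._scores.setdefault((lab, lab), 1.0)

    @staticmethod
    def _pair(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def lookup(self, a: str, b: str) -> float | None:
        return self._scores.get(self._pair(a, b))


class BondSimilarityTable(_PairTable):
    """Glycosidic-bond similarity scores.

    Lookup is total: the wildcard root bond matches anything with score
    1; identical labels score 1 even when unlisted; distinct unlisted
    pairs score 0 (conservative fallback).
    """

    def score(self, a: str, b: str) -> float:
        if a == WILDCARD_BOND or b == WILDCARD_BOND:
            return 1.0
        v = self.lookup(a, b)
        if v is not None:
            return v
        return 1.0 if a == b else 0.0

    @classmethod
    def default(cls) -> "BondSimilarityTable":
        return _default_bond_table()

    @classmethod
    def from_tsv(cls, text: str) -> "BondSimilarityTable":
        """Read a lower-triangular or full TSV matrix with label headers."""
        rows = [line.split("\t") for line in text.splitlines() if line.strip()]
        header = [h.strip() for h in rows[0][1:]]
        scores: dict[tuple[str, str], float] = {}
        for row in rows[1:]:
            row_label = row[0].strip()
            for col_label, cell in zip(header, row[1:]):
                cell = cell.strip()
                if cell:
                    scores[(row_label, col_label)] = float(cell)
        return cls(scores, header)


@lru_cache(maxsize=1)
def _default_bond_table() -> BondSimilarityTable:
    text = (
        resources.files("glyqgram") / "data" / "bond_similarity.tsv"
    ).read_text()
    return BondSimilarityTable.from_tsv(text)


class MonoSimilarityTable(_PairTable):
    """Monosaccharide similarity scores; identity by default."""

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        v = self.lookup(a, b)
        return v if v is not None else 0.0

    @classmethod
    def identity(cls) -> "MonoSimilarityTable":
        return cls({}, [])

    @classmethod
    def from_tsv(cls, text: str) -> "MonoSimilarityTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        scores = {}
        for r in df.index:
            for c in df.columns:
                v = df.loc[r, c]
                if pd.notna(v):
                    scores[(str(r), str(c))] = float(v)
        return cls(scores, [str(c) for c in df.columns])


def layer_similarity(l_i: int, l_j: int, *, formula: str = "reciprocal") -> float:
    """Similarity of two layers, from their distance.

    ``reciprocal`` (default): ``1 / (1 + |l_i - l_j|)``; ``exponential``:
    ``0.5 ** |l_i - l_j|``.  Both equal 1 at distance 0 and decrease
    strictly with distance.
    """
    if l_i < 0 or l_j < 0:
        raise GlycanError(f"layers must be non-negative, got {l_i}, {l_j}")
    d = abs(l_i - l_j)
    if formula == "reciprocal":
        return 1.0 / (1.0 + d)
    if formula == "exponential":
        return 0.5**d
    raise GlycanError(f"unknown layer similarity formula {formula!r}")


@dataclass
class LinkageTables:
    """Bundle of the three component tables used by LK scoring."""

    mono: MonoSimilarityTable
    bond: BondSimilarityTable
    layer_formula: str = "reciprocal"
    combine: str = "product"

    @classmethod
    def default(cls) -> "LinkageTables":
        return cls(MonoSimilarityTable.identity(), BondSimilarityTable.default())


def lk_similarity(a: QGram, b: QGram, tables: LinkageTables | None = None) -> float:
    """Linkage similarity between two q-grams of equal ``q``.

    Zero when the shapes differ; otherwise layer, per-position mono and
    per-position bond similarities combined under the canonical
    alignment (no re-matching across chains).
    """
    if a.q != b.q:
        raise GlycanError(f"q mismatch: {a.q} vs {b.q}")
    if tables is None:
        tables = LinkageTables.default()
    if a.shape != b.shape:
        return 0.0
    parts = [layer_similarity(a.layer, b.layer, formula=tables.layer_formula)]
    parts += [tables.mono.score(x, y) for x, y in zip(a.monos, b.monos)]
    parts += [tables.bond.score(x, y) for x, y in zip(a.bonds, b.bonds)]
    if tables.combine == "product":
        out = 1.0
        for p in parts:
            out *= p
        return out
    if tables.combine == "mean":
        return float(np.mean(parts))
    raise GlycanError(f"unknown combination rule {tables.combine!r}")


@dataclass
class SimilarityMatrix:
    """``d_q × d_q`` inter-q-gram similarity scores (pre-PSD-correction)."""

    q: int
    keys: list[str]
    values: np.ndarray
    method: str  # LK | KM | LKM

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.keys, columns=self.keys)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="key")


def lk_matrix(
    index: QGramIndex, tables: LinkageTables | None = None
) -> SimilarityMatrix:
    """LK similarity matrix over an index.

    Each key is assigned its corpus-representative layer (most frequent
    layer of that key, ties toward the root) before scoring.
    """
    if tables is None:
        tables = LinkageTables.default()
    reps = index.representatives()
    d = len(reps)
    values = np.zeros((d, d))
    for i in range(d):
        values[i, i] = lk_similarity(reps[i], reps[i], tables)
        for j in range(i + 1, d):
            v = lk_similarity(reps[i], reps[j], tables)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(index.q, index.keys, values, "LK")
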