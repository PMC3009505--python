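"""Rooted labeled glycan trees and KCF-style text I/O.

A glycan is modeled as a rooted tree: nodes carry monosaccharide labels
(``GlcNAc``, ``Gal``, ``Man``, ...) and each edge carries a glycosidic
bond label (``b1-4``, ``a2-3``, ``-6``, ...).  The root is the reducing
end of the sugar chain; a monosaccharide may be linked to at most four
child monosaccharides in addition to its parent.

Sibling order carries no chemical meaning, so trees are treated as
unordered; a canonical child ordering ``(bond code, child mono code,
child node id)`` is imposed everywhere that determinism matters
(serialization, q-gram enumeration).

The file format is a KCF (KEGG Chemical Function) dialect: records with
``ENTRY``/``NODE``/``EDGE`` blocks separated by ``///``.  Only the node
index, monosaccharide label and bond label are semantic; the 2-D layout
columns of full KCF are ignored on input and written as zeros.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

#: Reserved bond label for the (nonexistent) bond above the root.  Its
#: similarity to any bond is 1 so that it never penalizes a comparison.
WILDCARD_BOND = "*"


class GlycanError(ValueError):
    """Base class for glycan structure errors."""


class KCFParseError(GlycanError):
    """Malformed KCF text; the message names the offending line."""


class ValidationError(GlycanError):
    """A structurally invalid glycan (cycle, forest, missing root...)."""


_BOND_RE = re.compile(r"^([ab])?(\d+)?-(\d+)?$")


@dataclass(frozen=True)
class BondLabel:
    """A glycosidic bond label parsed into its optional components.

    The grammar is ``[anomer][donor]-[acceptor]`` where the anomer is
    ``a`` (alpha) or ``b`` (beta) and the positions are carbon numbers;
    any component may be absent (``b1-4``, ``-6``, ``b1-``, ``1-3``,
    ``-``).  The reserved wildcard ``*`` has all components unknown.
    """

    code: str
    anomer: str | None
    donor: str | None
    acceptor: str | None

    @classmethod
    def parse(cls, code: str) -> "BondLabel":
        if not code:
            raise GlycanError("empty bond label")
        if code == WILDCARD_BOND:
            return cls(code, None, None, None)
        m = _BOND_RE.match(code)
        if m is None:
            # open vocabulary: keep the code, components unknown
            return cls(code, None, None, None)
        return cls(code, m.group(1), m.group(2), m.group(3))


class Glycan:
    """A rooted, node- and edge-labeled glycan tree.

    Parameters
    ----------
    id : str
        Record identifier (e.g. a KEGG ``G`` number or a synthetic id).
    monos : dict
        Mapping ``node_id -> monosaccharide code``.
    parents : dict
        Mapping ``child_id -> (parent_id, bond code)``; the root is the
        unique node absent from this mapping.
    strict_degree : bool
        If True, more than four children is an error; otherwise a
        :class:`UserWarning` (the biological bound is a soft constraint).
    """

    def __init__(
        self,
        id: str,
        monos: dict[int, str],
        parents: dict[int, tuple[int, str]],
        *,
        strict_degree: bool = False,
    ) -> None:
        self.id = id
        self.monos = dict(monos)
        self.parents = dict(parents)
        self.root = self._find_root()
        self._children: dict[int, list[tuple[int, str]]] = {u: [] for u in self.monos}
        for child, (parent, bond) in self.parents.items():
            if parent not in self.monos:
                raise ValidationError(
                    f"edge references unknown parent node id {parent}"
                )
            if child not in self.monos:
                raise ValidationError(f"edge references unknown child node id {child}")
            self._children[parent].append((child, bond))
        for u in self._children:
            self._children[u].sort(key=lambda cb: (cb[1], self.monos[cb[0]], cb[0]))
        self._validate(strict_degree=strict_degree)

    # -- structure ---------------------------------------------------------

    def _find_root(self) -> int:
        if not self.monos:
            raise ValidationError("glycan has no nodes")
        roots = [u for u in self.monos if u not in self.parents]
        if not roots:
            raise ValidationError("no root: every node has a parent (cycle detected)")
        if len(roots) > 1:
            raise ValidationError(
                f"multiple roots: nodes {sorted(roots)} have no parent"
            )
        return roots[0]

    def _validate(self, strict_degree: bool) -> None:
        # BFS from root: with one parent per non-root node, full
        # reachability implies the edge relation is a connected tree.
        seen = set()
        stack = [self.root]
        while stack:
            u = stack.pop()
            if u in seen:
                raise ValidationError(f"cycle detected at node {u}")
            seen.add(u)
            stack.extend(c for c, _ in self._children[u])
        if len(seen) != len(self.monos):
            missing = sorted(set(self.monos) - seen)
            raise ValidationError(
                f"cycle detected: nodes {missing} unreachable from root"
            )
        for u, kids in self._children.items():
            if len(kids) > 4:
                msg = (
                    f"node {u} ({self.monos[u]}) has {len(kids)} children; "
                    "monosaccharides bond at most 4"
                )
                if strict_degree:
                    raise ValidationError(msg)
                warnings.warn(msg, UserWarning, stacklevel=3)
        for u, mono in self.monos.items():
            if not mono:
                raise ValidationError(f"node {u} has an empty monosaccharide label")

    @property
    def n_nodes(self) -> int:
        return len(self.monos)

    @property
    def n_edges(self) -> int:
        return len(self.parents)

    def children(self, u: int) -> list[tuple[int, str]]:
        """Children of ``u`` as ``(child_id, bond)`` in canonical order."""
        return self._children[u]

    def parent_bond(self, u: int) -> str:
        """Bond linking ``u`` to its parent; wildcard for the root."""
        if u == self.root:
            return WILDCARD_BOND
        return self.parents[u][1]

    def preorder(self) -> list[int]:
        """Node ids in deterministic pre-order (canonical child order)."""
        out: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(c for c, _ in reversed(self._children[u]))
        return out

    def layers(self) -> dict[int, int]:
        """Layer of each node: the number of linkages to the root.

        The root is at layer 0 and every child is one layer below its
        parent.
        """
        lay = {self.root: 0}
        stack = [self.root]
        while stack:
            u = stack.pop()
            for c, _ in self._children[u]:
                lay[c] = lay[u] + 1
                stack.append(c)
        return lay

    def subtree_nodes(self, u: int) -> list[int]:
        out = []
        stack = [u]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(c for c, _ in self._children[v])
        return out

    def relabeled(self) -> "Glycan":
        """Copy with nodes renumbered 1..n in canonical pre-order."""
        order = self.preorder()
        new_id = {u: i + 1 for i, u in enumerate(order)}
        monos = {new_id[u]: self.monos[u] for u in order}
        parents = {
            new_id[c]: (new_id[p], b) for c, (p, b) in self.parents.items()
        }
        return Glycan(self.id, monos, parents)

    def is_isomorphic(self, other: "Glycan") -> bool:
        """Label-isomorphism under the canonical (unordered) reading."""
        return _canon(self, self.root) == _canon(other, other.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Glycan(id={self.id!r}, nodes={self.n_nodes})"


def _canon(g: Glycan, u: int) -> tuple:
    kids = tuple(
        sorted((b, _canon(g, c)) for c, b in g.children(u))
    )
    return (g.monos[u], kids)


def layers(g: Glycan) -> dict[int, int]:
    """Module-level alias for :meth:`Glycan.layers`."""
    return g.layers()


# -- KCF I/O ---------------------------------------------------------------


def parse_kcf(text: str) -> Glycan:
    """Parse a single KCF record into a validated :class:`Glycan`.

    Edge lines are either real-KCF style ``idx child:b1 parent:4``
    (yielding bond ``b1-4``) or the simple four-column dialect
    ``idx child parent bond``.
    """
    entry_id = "G00000"
    node_lines: list[tuple[int, str]] = []
    edge_lines: list[tuple[int, str]] = []
    section = None
    saw_node = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.strip() == "///":
            continue
        tokens = line.split()
        head = tokens[0].upper()
        if head == "ENTRY":
            if len(tokens) > 1:
                entry_id = tokens[1]
            section = None
            continue
        if head == "NODE":
            section = "NODE"
            saw_node = True
            continue
        if head == "EDGE":
            section = "EDGE"
            continue
        if not raw[0].isspace() and head not in ("NODE", "EDGE"):
            # some other KCF block (BRACKET, COMPOSITION...): skip it
            section = None
            continue
        if section == "NODE":
            node_lines.append((lineno, line))
        elif section == "EDGE":
            edge_lines.append((lineno, line))
    if not saw_node:
        raise KCFParseError("no NODE block found")
    if not node_lines:
        raise KCFParseError("empty NODE block")

    monos: dict[int, str] = {}
    for lineno, line in node_lines:
        tokens = line.split()
        if len(tokens) < 2:
            raise KCFParseError(f"line {lineno}: malformed NODE line {line!r}")
        try:
            nid = int(tokens[0])
        except ValueError:
            raise KCFParseError(
                f"line {lineno}: non-integer node id in {line!r}"
            ) from None
        if nid in monos:
            raise KCFParseError(f"line {lineno}: duplicate node id {nid}")
        monos[nid] = tokens[1]

    parents: dict[int, tuple[int, str]] = {}
    for lineno, line in edge_lines:
        tokens = line.split()
        if len(tokens) < 3:
            raise KCFParseError(f"line {lineno}: malformed EDGE line {line!r}")
        child_id, left = _split_endpoint(tokens[1], lineno)
        parent_id, right = _split_endpoint(tokens[2], lineno)
        if len(tokens) >= 4:
            bond = tokens[3]
        elif left or right:
            bond = f"{left}-{right}"
        else:
            bond = "-"
        for nid in (child_id, parent_id):
            if nid not in monos:
                raise KCFParseError(
                    f"line {lineno}: edge references unknown node id {nid}"
                )
        if child_id in parents:
            raise KCFParseError(
                f"line {lineno}: node {child_id} has more than one parent"
            )
        parents[child_id] = (parent_id, bond)

    try:
        return Glycan(entry_id, monos, parents)
    except ValidationError as exc:
        raise KCFParseError(f"record {entry_id}: {exc}") from exc


def _split_endpoint(token: str, lineno: int) -> tuple[int, str]:
    node_part, _, bond_part = token.partition(":")
    try:
        return int(node_part), bond_part
    except ValueError:
        raise KCFParseError(
            f"line {lineno}: non-integer node id in edge endpoint {token!r}"
        ) from None


def write_kcf(g: Glycan) -> str:
    """Serialize a glycan to KCF text, deterministically.

    Nodes are renumbered 1..n in canonical pre-order, so two calls on
    label-isomorphic glycans produce byte-identical output.
    """
    order = g.preorder()
    new_id = {u: i + 1 for i, u in enumerate(order)}
    lines = [f"ENTRY       {g.id}          Glycan", f"NODE        {g.n_nodes}"]
    for u in order:
        lines.append(f"            {new_id[u]}   {g.monos[u]}   0   0")
    lines.append(f"EDGE        {g.n_edges}")
    eidx = 0
    for u in order:
        if u == g.root:
            continue
        parent, bond = g.parents[u]
        eidx += 1
        left, _, right = bond.partition("-")
        child_tok = f"{new_id[u]}:{left}" if left else str(new_id[u])
        parent_tok = f"{new_id[parent]}:{right}" if right else str(new_id[parent])
        lines.append(f"            {eidx}   {child_tok}   {parent_tok}")
    lines.append("///")
    return "\n".join(lines) + "\n"


def read_kcf(text: str) -> list[Glycan]:
    """Parse a multi-record KCF document (records separated by ``///``)."""
    return list(iter_kcf(text))


def iter_kcf(text: str) -> Iterator[Glycan]:
    for chunk in text.split("///"):
        if chunk.strip():
            yield parse_kcf(chunk)


def write_kcf_many(glycans: Iterable[Glycan]) -> str:
    return "".join(write_kcf(g) for g in glycans)


def read_labels(text: str) -> dict[str, int]:
    """Parse a two-column TSV ``glycan_id <TAB> label`` with labels ±1."""
    out: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GlycanError(f"labels line {lineno}: expected 2 columns")
        gid, lab = parts[0].strip(), parts[1].strip()
        value = int(lab)
        if value not in (-1, 1):
            raise GlycanError(f"labels line {lineno}: label must be +1 or -1")
        out[gid] = value
    return out


def write_labels(labels: dict[str, int]) -> str:
    return "".join(f"{gid}\t{lab:+d}\n" for gid, lab in labels.items())
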