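"""Synthetic glycan generation: random trees and planted-motif datasets.

Random glycans are grown top-down: starting from a root, each of a
node's child slots is filled independently with probability
``branch_prob``, truncated at ``max_depth``; node and bond labels are
drawn from configurable frequency tables.  The default label pools are
the 24 most frequent monosaccharides and 24 most frequent glycosidic
bonds of the KEGG glycan database census, with their database
occurrence frequencies (renormalized), so generated trees have a
realistic label composition (GlcNAc and b1-4 dominate).  Trees are
rejection-sampled until the node count falls in the configured range.

Two-class benchmark datasets plant a small motif fragment into every
positive glycan by replacing a uniformly chosen node at an allowed
layer with the motif root; the displaced children are reattached below
the motif's deepest leaf where degree permits, so trees stay valid.
This emulates a disease-associated substructure against a background of
unrelated glycans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Glycan, GlycanError

#: Monosaccharide occurrence frequencies in the KEGG glycan database
#: (top 24, including non-sugar node labels, which are treated as
#: ordinary labels).
DEFAULT_MONO_FREQS: dict[str, float] = {
    "GlcNAc": 0.1833, "Gal": 0.1712, "Man": 0.1486, "Glc": 0.1041,
    "LFuc": 0.042, "Neu5Ac": 0.0375, "S": 0.0371, "GalNAc": 0.0364,
    "LRha": 0.0225, "Xyl": 0.0198, "GlcA": 0.0159, "GlcN": 0.015,
    "*": 0.014, "Cer": 0.0116, "P": 0.0108, "Lgro-manHep": 0.0082,
    "Asn": 0.0076, "Kdo": 0.0069, "Fruf": 0.005, "LIdoA": 0.0049,
    "GalA": 0.0047, "LAraf": 0.0043, "Neu5Gc": 0.0035, "Galf": 0.0033,
}

#: Glycosidic bond occurrence frequencies (top 24), same census.
DEFAULT_BOND_FREQS: dict[str, float] = {
    "b1-4": 0.272, "a1-3": 0.1156, "b1-3": 0.0997, "a1-6": 0.0793,
    "b1-2": 0.0669, "a1-2": 0.0656, "a1-4": 0.0617, "b1-6": 0.0419,
    "a2-3": 0.0279, "-6": 0.0206, "a2-6": 0.0201, "-2": 0.0172,
    "b1-": 0.0145, "b1-1": 0.0134, "a1-": 0.0099, "-4": 0.0097,
    "-3": 0.0091, "-": 0.0053, "a1-5": 0.0052, "a2-8": 0.0037,
    "1-3": 0.0037, "1-": 0.0036, "1-4": 0.0036, "a2-4": 0.0025,
}


def _normalize(freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    if not freqs:
        raise GlycanError("empty frequency table")
    labels = list(freqs)
    p = np.array([freqs[k] for k in labels], dtype=float)
    if np.any(p < 0):
        raise GlycanError("negative frequency")
    total = p.sum()
    if total <= 0:
        raise GlycanError("frequencies sum to zero")
    return labels, p / total


@dataclass
class GeneratorConfig:
    """Random-glycan generator settings.

    Defaults: label frequencies from the database census above; trees
    of 5-15 nodes, at most 3 children per node (within the biological
    bound of 4), branching probability 0.3 per child slot — a slightly
    subcritical branching process whose typical tree is a handful of
    branches deep, like common N- and O-glycans.
    """

    mono_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MONO_FREQS)
    )
    bond_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOND_FREQS)
    )
    max_depth: int = 7
    max_children: int = 3
    branch_prob: float = 0.3
    min_nodes: int = 5
    max_nodes: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_children <= 4:
            raise GlycanError("max_children must be between 1 and 4")
        if self.min_nodes < 1 or self.min_nodes > self.max_nodes:
            raise GlycanError("need 1 <= min_nodes <= max_nodes")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise GlycanError("branch_prob must be a probability")
        if self.max_depth < 0:
            raise GlycanError("max_depth must be >= 0")
        c, d = self.max_children, self.max_depth
        reachable = d + 1 if c == 1 else (c ** (d + 1) - 1) // (c - 1)
        if reachable < self.min_nodes:
            raise GlycanError(
                f"min_nodes={self.min_nodes} unreachable at depth {d} with "
                f"{c} children per node"
            )


@dataclass
class MotifSpec:
    """A small fragment planted into positive-class glycans.

    ``graft_layer_range`` bounds (inclusive) the layer at which the
    fragment root may be grafted.
    """

    fragment: Glycan
    graft_layer_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        lo, hi = self.graft_layer_range
        if lo < 0 or lo > hi:
            raise GlycanError("invalid graft layer range")

    @property
    def depth(self) -> int:
        return max(self.fragment.layers().values())


def random_glycan(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    id: str = "SYN",
    max_attempts: int = 10_000,
) -> Glycan:
    """Draw one random glycan; rejection-sampled to the node-count range."""
    mono_labels, mono_p = _normalize(cfg.mono_freqs)
    bond_labels, bond_p = _normalize(cfg.bond_freqs)
    for _ in range(max_attempts):
        monos: dict[int, str] = {}
        parents: dict[int, tuple[int, str]] = {}
        next_id = [1]

        def grow(depth: int, parent: int | None, bond: str | None) -> None:
            u = next_id[0]
            next_id[0] += 1
            monos[u] = mono_labels[rng.choice(len(mono_labels), p=mono_p)]
            if parent is not None:
                parents[u] = (parent, bond)
            if depth >= cfg.max_depth:
                return
            for _slot in range(cfg.max_children):
                if len(monos) > cfg.max_nodes:
                    break  # already over budget: stop early, reject below
                if rng.random() < cfg.branch_prob:
                    b = bond_labels[rng.choice(len(bond_labels), p=bond_p)]
                    grow(depth + 1, u, b)

        grow(0, None, None)
        if cfg.min_nodes <= len(monos) <= cfg.max_nodes:
            return Glycan(id, monos, parents)
    raise GlycanError(
        f"could not draw a tree with {cfg.min_nodes}-{cfg.max_nodes} nodes "
        f"in {max_attempts} attempts; config is infeasible or too tight"
    )


def _graft(g: Glycan, motif: MotifSpec, rng: np.random.Generator) -> Glycan:
    """Replace one node of ``g`` (at an allowed layer) by the motif root."""
    lay = g.layers()
    lo, hi = motif.graft_layer_range
    candidates = sorted(u for u, l in lay.items() if lo <= l <= hi)
    if not candidates:
        candidates = sorted(
            u for u, l in lay.items() if l == max(lay.values())
        )
    site = candidates[rng.choice(len(candidates))]

    removed = set(g.subtree_nodes(site))
    monos = {u: m for u, m in g.monos.items() if u not in removed}
    parents = {
        c: pb for c, pb in g.parents.items() if c not in removed and pb[0] not in removed
    }
    offset = max(g.monos) + 1
    frag = motif.fragment
    frag_id = {u: offset + i for i, u in enumerate(frag.preorder())}
    for u in frag.preorder():
        monos[frag_id[u]] = frag.monos[u]
    for c, (p, b) in frag.parents.items():
        parents[frag_id[c]] = (frag_id[p], b)
    if site != g.root:
        parent, bond = g.parents[site]
        parents[frag_id[frag.root]] = (parent, bond)

    # reattach the displaced children under the motif's deepest leaf
    frag_lay = frag.layers()
    deepest = max(frag.preorder(), key=lambda u: (frag_lay[u], -u))
    attach = frag_id[deepest]
    slots = 4 - len(frag.children(deepest))
    for child, (_, bond) in sorted(
        (c, pb) for c, pb in g.parents.items() if pb[0] == site and c in removed
    ):
        if slots <= 0:
            break  # degree full: drop the remaining displaced subtrees
        keep = set(g.subtree_nodes(child))
        for u in sorted(keep):
            monos[u] = g.monos[u]
            if u != child:
                parents[u] = g.parents[u]
        parents[child] = (attach, bond)
        slots -= 1
    return Glycan(g.id, monos, parents).relabeled()


def planted_dataset(
    n_pos: int,
    n_neg: int,
    motif: MotifSpec,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Glycan], np.ndarray]:
    """Two-class dataset: motif-bearing positives vs background negatives.

    Every positive glycan contains at least one embedding of the motif
    fragment; negatives are background draws.  Labels are +1/-1 aligned
    with the glycan list.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if motif.depth > cfg.max_depth:
        raise GlycanError(
            f"motif depth {motif.depth} exceeds generator max_depth "
            f"{cfg.max_depth}"
        )
    glycans: list[Glycan] = []
    labels = np.concatenate(
        [np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)]
    )
    for i in range(n_pos):
        g = random_glycan(cfg, rng, id=f"POS{i + 1:04d}")
        g = _graft(g, motif, rng)
        if not contains_fragment(g, motif.fragment):  # pragma: no cover
            raise GlycanError(f"graft failed to embed the motif in {g.id}")
        glycans.append(g)
    for i in range(n_neg):
        glycans.append(random_glycan(cfg, rng, id=f"NEG{i + 1:04d}"))
    return glycans, labels


def contains_fragment(g: Glycan, fragment: Glycan) -> bool:
    """Exhaustive rooted-subtree search for an exact fragment embedding.

    An embedding maps the fragment root to any node of ``g`` and each
    fragment child to a distinct child of its parent's image with equal
    monosaccharide and bond labels.
    """

    def match(u_frag: int, u_g: int) -> bool:
        if fragment.monos[u_frag] != g.monos[u_g]:
            return False
        needed = fragment.children(u_frag)
        if not needed:
            return True
        available = g.children(u_g)
        return _injective_match(needed, available, match)

    return any(match(fragment.root, u) for u in g.preorder())


def _injective_match(needed, available, match) -> bool:
    if not needed:
        return True
    (child, bond), rest = needed[0], needed[1:]
    for i, (cand, cand_bond) in enumerate(available):
        if cand_bond == bond and match(child, cand):
            if _injective_match(rest, available[:i] + available[i + 1 :], match):
                return True
    return False
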