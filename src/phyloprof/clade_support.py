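"""Clade support across bootstrap tree samples and support-vs-removal curves.

Support for a clade is the fraction of sample trees containing the exact
bipartition (clade | rest); no partial or compatibility credit is given,
matching bootstrap-proportion semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .seqio_trees import Bipartition, Tree, TreeSample, parse_newick

__all__ = [
    "CladeQuery",
    "SupportCurve",
    "clade_frequency",
    "majority_consensus",
    "support_curve",
]


@dataclass(frozen=True)
class CladeQuery:
    """A taxon set whose monophyly is interrogated within a universe."""

    taxa: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.taxa:
            raise ValueError("empty clade query")
        if not self.taxa <= self.universe:
            unknown = sorted(self.taxa - self.universe)
            raise ValueError(f"query taxa not in universe: {unknown}")


@dataclass
class SupportCurve:
    """Ordered (fraction_removed, support, n_trees) points."""

    points: list

    def __post_init__(self) -> None:
        fracs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("fractions must be strictly increasing")
        if any(not (0 <= p[1] <= 1) for p in self.points):
            raise ValueError("supports must lie in [0, 1]")

    @property
    def fractions(self) -> list:
        return [p[0] for p in self.points]

    @property
    def supports(self) -> list:
        return [p[1] for p in self.points]


def clade_frequency(sample: TreeSample, query: CladeQuery) -> float:
    """Fraction of sample trees containing the split (query.taxa | rest).

    Trivial queries (single taxon, all-but-one, or the full set) are present
    in every tree by definition and return 1.0 with a warning.
    """
    if query.universe != sample.taxa:
        unknown = sorted(query.universe - sample.taxa)
        if unknown:
            raise ValueError(f"query universe has taxa unknown to the sample: {unknown}")
        raise ValueError("query universe differs from sample taxa")
    n = len(query.universe)
    k = len(query.taxa)
    if k in (1, n - 1, n):
        warnings.warn(
            f"trivial clade query of size {k} over {n} taxa; support is 1.0 by definition",
            stacklevel=2,
        )
        return 1.0
    target = Bipartition.canonical(query.taxa, query.universe)
    hits = sum(1 for tree in sample.trees if target in tree.bipartitions())
    return hits / len(sample.trees)


def _split_counts(sample: TreeSample) -> dict:
    counts: dict = {}
    for tree in sample.trees:
        for bip in tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    return counts


def majority_consensus(sample: TreeSample, threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: splits with frequency strictly above ``threshold``.

    Retained edges carry their frequency as the internal-node label.  For
    ``threshold >= 0.5`` the retained splits are pairwise compatible by
    construction.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    n_trees = len(sample.trees)
    universe = sample.taxa
    anchor = min(universe)
    retained = [
        (bip, c / n_trees)
        for bip, c in _split_counts(sample).items()
        if c / n_trees > threshold
    ]
    # canonical sides exclude the anchor taxon, so sides form clades of a
    # tree rooted on the anchor's edge; compatible sides are laminar.
    retained.sort(key=lambda t: (-len(t[0].side), sorted(t[0].side)))

    class _Node:
        __slots__ = ("leafset", "children", "support")

        def __init__(self, leafset, support=None):
            self.leafset = set(leafset)
            self.children: list = []
            self.support = support

    root = _Node(universe)
    root.children = [_Node([t]) for t in sorted(universe)]
    for bip, freq in retained:
        side = bip.side
        # descend to the smallest node properly containing the side
        node = root
        while True:
            nxt = next(
                (c for c in node.children if side < c.leafset), None
            )
            if nxt is None:
                break
            node = nxt
        moved = [c for c in node.children if c.leafset <= side]
        covered = set().union(*(c.leafset for c in moved)) if moved else set()
        if covered != side:
            raise ValueError(
                f"split {sorted(side)} incompatible with higher-frequency splits"
            )
        new = _Node(side, support=freq)
        new.children = moved
        node.children = [c for c in node.children if c not in moved] + [new]

    def _newick(node: _Node) -> str:
        if not node.children:
            return next(iter(node.leafset))
        inner = ",".join(_newick(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}"

    return parse_newick(_newick(root) + ";")


def support_curve(samples, query: CladeQuery) -> SupportCurve:
    """One (fraction, clade_frequency, n_trees) point per (fraction, sample) pair."""
    samples = sorted(samples, key=lambda t: t[0])
    fracs = [f for f, _ in samples]
    if len(set(fracs)) != len(fracs):
        dup = sorted({f for f in fracs if fracs.count(f) > 1})
        raise ValueError(f"duplicate fractions in curve input: {dup}")
    for _, sample in samples:
        if sample.taxa != query.universe:
            raise ValueError("all samples must share the query's taxon universe")
    points = [
        (f, clade_frequency(sample, query), len(sample.trees)) for f, sample in samples
    ]
    return SupportCurve(points=points)
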