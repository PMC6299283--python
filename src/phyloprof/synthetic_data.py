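"""Seeded generators for every pipeline input, with known ground truth.

All generators are fully deterministic: the same seed and parameters give
byte-identical outputs (numpy integer-state generators, no time seeding).
Amino-acid evolution uses an equal-exchangeability, uniform-frequency
20-state process; rate ranking, not model realism, is what downstream
stages exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqio_trees import Alignment, Bipartition, SequenceRecord, Tree, TreeSample, parse_newick
from .site_stripping import SiteRates

__all__ = [
    "AMINO_ACIDS",
    "GroupSpec",
    "HitComposition",
    "SimulationConfig",
    "simulate_tree",
    "simulate_alignment_with_rates",
    "simulate_tree_sample",
    "simulate_profiles",
    "simulate_hit_table",
    "two_block_retention",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
N_STATES = 20


@dataclass
class GroupSpec:
    """A species group with a retention probability per ortholog.

    ``retention`` is either a scalar applied to every ortholog or a vector
    of per-ortholog probabilities.
    """

    name: str
    n_species: int
    retention: object

    def probabilities(self, n_orthologs: int) -> np.ndarray:
        p = np.asarray(self.retention, dtype=float)
        if p.ndim == 0:
            p = np.full(n_orthologs, float(p))
        if p.shape != (n_orthologs,):
            raise ValueError(
                f"group {self.name!r}: retention length {p.shape} != {n_orthologs}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"group {self.name!r}: probabilities must be in [0, 1]")
        return p


@dataclass
class HitComposition:
    """Planted query-class counts for a simulated hit table."""

    n_target: int = 0
    n_prokaryote: int = 0
    n_host_first: int = 0
    n_no_hit: int = 0
    n_host_identity: int = 0

    def total(self) -> int:
        return (
            self.n_target
            + self.n_prokaryote
            + self.n_host_first
            + self.n_no_hit
            + self.n_host_identity
        )

    def __post_init__(self) -> None:
        for f in (
            self.n_target,
            self.n_prokaryote,
            self.n_host_first,
            self.n_no_hit,
            self.n_host_identity,
        ):
            if f < 0:
                raise ValueError("composition counts must be non-negative")


@dataclass
class SimulationConfig:
    """Bundle of generator parameters for the `simulate` CLI."""

    seed: int = 1
    n_taxa: int = 12
    alignment_length: int = 1000
    gamma_shape: float = 0.5
    conflict_fraction: float = 0.15
    planted_frequency: float = 0.7
    n_trees: int = 1000
    n_orthologs: int = 300
    groups: list = field(
        default_factory=lambda: [
            GroupSpec("g1", 5, 0.9),
            GroupSpec("g2", 5, 0.1),
        ]
    )
    hit_composition: HitComposition = field(
        default_factory=lambda: HitComposition(10, 5, 5, 5, 5)
    )


# ---------------------------------------------------------------------------
# Trees

def simulate_tree(n_taxa: int, seed: int) -> Tree:
    """Random binary unrooted tree with leaves t001..tN and exponential
    branch lengths (mean 0.15), built by random sequential addition."""
    if n_taxa < 4:
        raise ValueError(f"need at least 4 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1:03d}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    for lab in labels[:3]:
        child = dendropy.Node()
        child.taxon = taxa.get_taxon(lab)
        root.add_child(child)
    for lab in labels[3:]:
        edges = [
            node for node in tree.preorder_node_iter() if node is not root
        ]
        host = edges[rng.integers(len(edges))]
        parent = host.parent_node
        mid = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(mid)
        mid.add_child(host)
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(lab)
        mid.add_child(leaf)
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = float(rng.exponential(0.15)) + 1e-3
    return Tree(tree)


def _find_split_node(dtree: dendropy.Tree, focal: Bipartition):
    """Internal node whose leaf set realizes the focal split (either side)."""
    universe = focal.universe
    sides = (focal.side, focal.universe - focal.side)
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node or node.is_leaf():
            continue
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        if leafset in sides and 2 <= len(leafset) <= len(universe) - 2:
            return node
    return None


def _nni_variants(tree: Tree, focal: Bipartition) -> list:
    """All NNI rearrangements across the focal edge (none contain the split)."""
    variants = []
    base_newick = tree.newick()
    probe = parse_newick(base_newick)
    node = _find_split_node(probe._dtree, focal)
    if node is None:
        raise ValueError("focal bipartition is not an edge of the tree")
    n_children = len(node.child_nodes())
    n_sibs = len(node.parent_node.child_nodes()) - 1
    for ci in range(n_children):
        for si in range(n_sibs):
            t = parse_newick(base_newick)
            nd = _find_split_node(t._dtree, focal)
            parent = nd.parent_node
            child = nd.child_nodes()[ci]
            sib = [c for c in parent.child_nodes() if c is not nd][si]
            nd.remove_child(child)
            parent.remove_child(sib)
            nd.add_child(sib)
            parent.add_child(child)
            variants.append(Tree(t._dtree))
    return variants


def simulate_tree_sample(
    base_tree: Tree,
    focal: Bipartition,
    p: float,
    n_trees: int,
    seed: int,
) -> TreeSample:
    """A sample in which each tree independently keeps the focal edge with
    probability ``p`` and otherwise carries one NNI across it."""
    if not (0 <= p <= 1):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if focal not in base_tree.bipartitions():
        raise ValueError("focal bipartition is not present in the base tree")
    rng = np.random.default_rng(seed)
    variants = _nni_variants(base_tree, focal)
    keep = rng.random(n_trees) < p
    picks = rng.integers(len(variants), size=n_trees)
    trees = [base_tree if k else variants[i] for k, i in zip(keep, picks)]
    return TreeSample(trees=trees, taxa=base_tree.taxa)


# ---------------------------------------------------------------------------
# Alignments

def _evolve_on_tree(
    dtree: dendropy.Tree, rates: np.ndarray, rng: np.random.Generator
) -> dict:
    """Evolve sites under the 20-state equal-exchangeability process; returns
    {leaf label: state index array}."""
    L = rates.size
    states: dict = {}
    leaves: dict = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            states[node] = rng.integers(0, N_STATES, L)
        else:
            t = node.edge.length or 0.0
            # P(any replacement event) under total rate 20/19 gives the
            # standard K-state equal-rates transition probabilities
            c = 1.0 - np.exp(-(N_STATES / (N_STATES - 1)) * rates * t)
            parent_states = states[node.parent_node]
            hit = rng.random(L) < c
            redraw = rng.integers(0, N_STATES, L)
            states[node] = np.where(hit, redraw, parent_states)
        if node.is_leaf():
            leaves[node.taxon.label] = states[node]
    return leaves


def simulate_alignment_with_rates(
    tree: Tree,
    length: int,
    gamma_shape: float,
    conflict_fraction: float,
    seed: int,
    conflict_split: Optional[Bipartition] = None,
) -> tuple:
    """Simulate an alignment with gamma-distributed site rates and an
    optional conflicting-signal block in the fastest sites.

    Per-site rate multipliers are gamma(shape, mean 1).  The
    ``conflict_fraction`` of sites with the highest multipliers are evolved
    on an NNI rearrangement across ``conflict_split`` (or a random internal
    edge) instead of ``tree``.  Returns ``(Alignment, SiteRates, frozenset
    of conflict column indices)``; the rates returned are the true
    multipliers.
    """
    if length < 20:
        raise ValueError("alignment length must be >= 20")
    if not (0 <= conflict_fraction <= 1):
        raise ValueError(f"conflict_fraction must be in [0, 1], got {conflict_fraction}")
    if gamma_shape <= 0:
        raise ValueError("gamma_shape must be positive")
    rng = np.random.default_rng(seed)
    rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
    n_conflict = int(np.floor(conflict_fraction * length + 0.5))
    order = np.lexsort((np.arange(length), -rates))
    conflict_idx = frozenset(order[:n_conflict].tolist())
    taxa_order = sorted(tree.taxa)
    columns = np.empty((len(taxa_order), length), dtype=int)

    main_mask = np.array([i not in conflict_idx for i in range(length)])
    main_leaves = _evolve_on_tree(tree._dtree, rates[main_mask], rng)
    for r, lab in enumerate(taxa_order):
        columns[r, main_mask] = main_leaves[lab]
    if n_conflict:
        if conflict_split is None:
            splits = sorted(
                tree.bipartitions(), key=lambda b: (len(b.side), sorted(b.side))
            )
            conflict_split = splits[rng.integers(len(splits))]
        alt = _nni_variants(tree, conflict_split)[0]
        alt_leaves = _evolve_on_tree(alt._dtree, rates[~main_mask], rng)
        for r, lab in enumerate(taxa_order):
            columns[r, ~main_mask] = alt_leaves[lab]
    records = [
        SequenceRecord(lab, "".join(AMINO_ACIDS[columns[r]]))
        for r, lab in enumerate(taxa_order)
    ]
    return Alignment(records), SiteRates(rates), conflict_idx


# ---------------------------------------------------------------------------
# Profiles

def two_block_retention(
    n_orthologs: int, n_groups: int, high: float = 0.9, low: float = 0.1
) -> list:
    """Complementary per-ortholog retention vectors: group g retains its own
    ortholog block with probability ``high`` and the rest with ``low``."""
    bounds = np.linspace(0, n_orthologs, n_groups + 1).astype(int)
    vectors = []
    for g in range(n_groups):
        v = np.full(n_orthologs, low)
        v[bounds[g] : bounds[g + 1]] = high
        vectors.append(v)
    return vectors


def simulate_profiles(
    groups: Sequence[GroupSpec], n_orthologs: int, seed: int
) -> tuple:
    """Species x ortholog count table with planted group structure.

    Presence is Bernoulli per species with its group's per-ortholog
    retention probability; present cells get count 1 or 2 (to exercise
    binarization).  Returns ``(counts DataFrame, {species: group name})``.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n_species < 2:
            raise ValueError(f"group {g.name!r} needs at least 2 species")
    rng = np.random.default_rng(seed)
    rows = []
    species = []
    truth: dict = {}
    for g in groups:
        p = g.probabilities(n_orthologs)
        for s in range(g.n_species):
            name = f"{g.name}_s{s + 1:02d}"
            present = rng.random(n_orthologs) < p
            counts = np.where(present, 1 + (rng.random(n_orthologs) < 0.2), 0)
            rows.append(counts)
            species.append(name)
            truth[name] = g.name
    orthologs = [f"og{j + 1:04d}" for j in range(n_orthologs)]
    return pd.DataFrame(np.array(rows), index=species, columns=orthologs), truth


# ---------------------------------------------------------------------------
# Hit tables

_EUK_SPECIES = [f"Fungus_sp{i}" for i in range(1, 7)] + [
    "Amoeba_sp1",
    "Choanoflagellate_sp1",
]
_HOST_SPECIES = [f"Stramenopile_sp{i}" for i in range(1, 4)]
_BACT_SPECIES = [f"Bacterium_sp{i}" for i in range(1, 5)]
_ARCH_SPECIES = ["Archaeon_sp1", "Archaeon_sp2"]
_VIR_SPECIES = ["Virus_sp1"]


def _ranked_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    start = rng.uniform(200, 400)
    drops = rng.uniform(1, 20, size=n - 1) if n > 1 else np.array([])
    return start - np.concatenate([[0.0], np.cumsum(drops)])


def _emit_hits(
    rows: list,
    rng: np.random.Generator,
    query: str,
    species_kingdom: list,
) -> None:
    scores = _ranked_scores(rng, len(species_kingdom))
    for rank, ((species, kingdom, flags), score) in enumerate(
        zip(species_kingdom, scores), start=1
    ):
        rows.append(
            {
                "qseqid": query,
                "sseqid": f"{species}|p{rng.integers(1, 10_000)}",
                "rank": rank,
                "pident": round(float(rng.uniform(30, 90)), 1),
                "evalue": float(10.0 ** -rng.uniform(10, 50)),
                "bitscore": round(float(max(score, 25.0)), 1),
                "superkingdom": kingdom,
                "lineage_flags": flags,
                "species": species,
            }
        )


def simulate_hit_table(composition: HitComposition, seed: int) -> tuple:
    """Ranked homology-hit table with planted per-query classes.

    Classes: ``target`` (clean eukaryote), ``prokaryote`` (bestsum lands on
    Bacteria/Archaea/Viruses), ``host_first`` (rank-1 hit flagged
    stramenopile), ``no_hit`` (zero rows), ``host_identity`` (eukaryote but
    100% or >95% identical to a host protein).  Returns ``(hits DataFrame,
    truth DataFrame with columns query, label, host_identity)``.
    """
    if composition.total() < 1:
        raise ValueError("hit composition is empty")
    rng = np.random.default_rng(seed)
    rows: list = []
    truth_rows: list = []
    qid = 0

    def next_query() -> str:
        nonlocal qid
        qid += 1
        return f"contig{qid:05d}"

    for _ in range(composition.n_target):
        q = next_query()
        n = int(rng.integers(3, 11))
        picks = [
            (sp, "Eukaryota", "") for sp in rng.choice(_EUK_SPECIES, size=n)
        ]
        _emit_hits(rows, rng, q, picks)
        truth_rows.append(
            {"query": q, "label": "target", "host_identity": round(float(rng.uniform(20, 90)), 1)}
        )
    for _ in range(composition.n_prokaryote):
        q = next_query()
        kind = rng.integers(3)
        pool, kingdom = (
            (_BACT_SPECIES, "Bacteria"),
            (_ARCH_SPECIES, "Archaea"),
            (_VIR_SPECIES, "Viruses"),
        )[kind]
        n = int(rng.integers(2, 8))
        picks = [(sp, kingdom, "") for sp in rng.choice(pool, size=n)]
        _emit_hits(rows, rng, q, picks)
        truth_rows.append(
            {"query": q, "label": "prokaryote", "host_identity": round(float(rng.uniform(20, 90)), 1)}
        )
    for _ in range(composition.n_host_first):
        q = next_query()
        n = int(rng.integers(2, 8))
        picks = [(str(rng.choice(_HOST_SPECIES)), "Eukaryota", "stramenopile")]
        picks += [(sp, "Eukaryota", "") for sp in rng.choice(_EUK_SPECIES, size=n - 1)]
        _emit_hits(rows, rng, q, picks)
        truth_rows.append(
            {"query": q, "label": "host_first", "host_identity": round(float(rng.uniform(20, 90)), 1)}
        )
    for _ in range(composition.n_no_hit):
        q = next_query()
        truth_rows.append({"query": q, "label": "no_hit", "host_identity": np.nan})
    for _ in range(composition.n_host_identity):
        q = next_query()
        n = int(rng.integers(3, 11))
        picks = [(sp, "Eukaryota", "") for sp in rng.choice(_EUK_SPECIES, size=n)]
        _emit_hits(rows, rng, q, picks)
        ident = 100.0 if rng.random() < 0.5 else round(float(rng.uniform(95.01, 99.9)), 2)
        truth_rows.append({"query": q, "label": "host_identity", "host_identity": ident})

    hits = pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "rank", "pident", "evalue", "bitscore",
        "superkingdom", "lineage_flags", "species",
    ])
    truth = pd.DataFrame(truth_rows, columns=["query", "label", "host_identity"])
    return hits, truth
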