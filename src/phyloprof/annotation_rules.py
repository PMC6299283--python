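"""Deterministic annotation rule engines.

Covers the decontamination screens (bestsum taxonomic assignment, cellular
origin filter, host first-hit filter, host-identity filter, 100%-identity
deduplication), MCL protein-family clustering with the >= 3 organisms
retention rule, KEGG-ortholog ID transfer at the 80% bit-score threshold,
and thresholded presence/absence calling.

All engines are pure functions of their tabular inputs: identical tables
give identical keep/discard sets regardless of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NO_HIT",
    "CELLULAR_SUPERKINGDOMS",
    "HitRecord",
    "TaxonAssignment",
    "KeggTransferDecision",
    "DecontamReport",
    "read_hit_table",
    "hits_from_frame",
    "assign_taxon_bestsum",
    "screen_cellular_origin",
    "screen_host_first_hit",
    "screen_host_identity",
    "dedup_identical",
    "mcl_cluster",
    "filter_clusters_by_organisms",
    "decide_kegg_transfer",
    "transfer_kegg_ids",
    "build_presence_matrix",
    "run_decontamination",
]

NO_HIT = "NO_HIT"
CELLULAR_SUPERKINGDOMS = frozenset({"Bacteria", "Archaea", "Eukaryota", "Viruses"})
HOST_FLAG = "stramenopile"

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "rank",
    "pident",
    "evalue",
    "bitscore",
    "superkingdom",
    "lineage_flags",
    "species",
]


@dataclass(frozen=True)
class HitRecord:
    """One ranked homology hit with taxonomy."""

    query: str
    subject: str
    rank: int
    bitscore: float
    evalue: float
    percent_identity: float
    superkingdom: str
    lineage_flags: frozenset
    species: str

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and evalue must be non-negative")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")


@dataclass(frozen=True)
class TaxonAssignment:
    query: str
    species: str
    superkingdom: Optional[str]
    score: float


@dataclass(frozen=True)
class KeggTransferDecision:
    transfer: bool
    uniprot_best_bit: float
    kegg_best_bit: Optional[float]
    reason: str


@dataclass
class DecontamReport:
    """Per-stage retained/removed query sets of the decontamination pipeline."""

    assignments: dict
    removed_cellular: set
    removed_host_first: set
    removed_host_identity: set
    kept: set

    def counts(self) -> dict:
        return {
            "input": len(self.assignments),
            "removed_cellular": len(self.removed_cellular),
            "removed_host_first": len(self.removed_host_first),
            "removed_host_identity": len(self.removed_host_identity),
            "kept": len(self.kept),
        }


# ---------------------------------------------------------------------------
# Hit table I/O

def hits_from_frame(df: pd.DataFrame) -> dict:
    """Group a hit table into {query: [HitRecord sorted by rank]}."""
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    out: dict = {}
    for row in df.itertuples(index=False):
        flags = getattr(row, "lineage_flags")
        if isinstance(flags, str):
            flagset = frozenset(f for f in flags.split(";") if f)
        elif flags is None or (isinstance(flags, float) and np.isnan(flags)):
            flagset = frozenset()
        else:
            flagset = frozenset(flags)
        rec = HitRecord(
            query=str(row.qseqid),
            subject=str(row.sseqid),
            rank=int(row.rank),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
            percent_identity=float(row.pident),
            superkingdom=str(row.superkingdom),
            lineage_flags=flagset,
            species=str(row.species),
        )
        out.setdefault(rec.query, []).append(rec)
    for query, hits in out.items():
        hits.sort(key=lambda h: h.rank)
        ranks = [h.rank for h in hits]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"duplicate ranks for query {query!r}")
        scores = [h.bitscore for h in hits]
        if any(b > a + 1e-9 for a, b in zip(scores, scores[1:])):
            raise ValueError(f"bitscores increase with rank for query {query!r}")
    return out


def read_hit_table(path) -> dict:
    return hits_from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Decontamination screens

def assign_taxon_bestsum(hits: Sequence[HitRecord], top_n: int = 10) -> TaxonAssignment:
    """Assign a query to the species with the largest summed bit score over
    its ``top_n`` first hits; no hits gives ``NO_HIT``.

    Ties on the summed score are broken by the species owning the single
    highest-scoring hit, then by lexicographic species label.
    """
    hits = sorted(hits, key=lambda h: h.rank)
    if not hits:
        return TaxonAssignment(query="", species=NO_HIT, superkingdom=None, score=0.0)
    query = hits[0].query
    if any(h.query != query for h in hits):
        raise ValueError("assign_taxon_bestsum expects hits of a single query")
    considered = [h for h in hits if h.rank <= top_n]
    sums: dict = {}
    best_single: dict = {}
    kingdom: dict = {}
    for h in considered:
        sums[h.species] = sums.get(h.species, 0.0) + h.bitscore
        best_single[h.species] = max(best_single.get(h.species, 0.0), h.bitscore)
        kingdom.setdefault(h.species, h.superkingdom)
    winner = min(
        sums, key=lambda sp: (-sums[sp], -best_single[sp], sp)
    )
    return TaxonAssignment(
        query=query,
        species=winner,
        superkingdom=kingdom[winner],
        score=sums[winner],
    )


def screen_cellular_origin(assignments: Iterable[TaxonAssignment]) -> dict:
    """Keep eukaryote-assigned queries; remove NO_HIT, Bacteria, Archaea, Viruses.

    Returns {query: keep_bool}.
    """
    out: dict = {}
    for a in assignments:
        if a.species == NO_HIT:
            out[a.query] = False
            continue
        if a.superkingdom not in CELLULAR_SUPERKINGDOMS:
            raise ValueError(
                f"unknown superkingdom {a.superkingdom!r} for query {a.query!r}"
            )
        out[a.query] = a.superkingdom == "Eukaryota"
    return out


def screen_host_first_hit(
    hits: Sequence[HitRecord], evalue_cutoff: float = 1e-10
) -> bool:
    """True (keep) unless the first hit passing the e-value cutoff is
    flagged as the host lineage (stramenopile)."""
    qualifying = [h for h in sorted(hits, key=lambda h: h.rank) if h.evalue <= evalue_cutoff]
    if not qualifying:
        return True
    return HOST_FLAG not in qualifying[0].lineage_flags


def screen_host_identity(best_identity: Optional[float]) -> bool:
    """True (keep) unless best identity to a host protein is 100% or > 95%."""
    if best_identity is None:
        return True
    if not (0 <= best_identity <= 100):
        raise ValueError(f"percent identity out of range: {best_identity}")
    return not (best_identity == 100.0 or best_identity > 95.0)


def dedup_identical(peptides: Mapping[str, str], exact_only: bool = False) -> tuple:
    """Collapse 100%-identity redundancy in a peptide set.

    Drops exact duplicates and (unless ``exact_only``) sequences that are
    exact substrings of a retained longer sequence.  The longest sequence is
    retained (ties: lexicographically smallest id).  Returns
    ``(retained: dict, cluster_map: dict dropped_id -> representative_id)``.
    """
    if not peptides:
        raise ValueError("empty peptide set")
    order = sorted(peptides, key=lambda pid: (-len(peptides[pid]), pid))
    retained: dict = {}
    cluster_map: dict = {}
    for pid in order:
        seq = peptides[pid]
        rep = None
        for rid, rseq in retained.items():
            if seq == rseq or (not exact_only and seq in rseq):
                rep = rid
                break
        if rep is None:
            retained[pid] = seq
        else:
            cluster_map[pid] = rep
    return retained, cluster_map


# ---------------------------------------------------------------------------
# MCL family clustering

def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list:
    """Markov clustering of a positive-weight similarity graph.

    Adds unit self-loops, column-normalizes, then alternates expansion
    (matrix squaring) and inflation (elementwise power + renormalization),
    pruning entries below ``prune``, until the largest entry change drops
    below ``tol`` or ``max_iter`` is reached.  Clusters are the weakly
    connected components of the converged matrix's nonzero structure, a
    partition of the nodes.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u!r}, {v!r}): {w}")
        if u == v:
            continue
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        delta = np.abs(inflated - M).max()
        M = inflated
        if delta < tol:
            break
    adj = (M + M.T) > 0
    _, comp = connected_components(adj, directed=False)
    clusters: dict = {}
    for v, i in index.items():
        clusters.setdefault(comp[i], set()).add(v)
    return sorted(
        (frozenset(c) for c in clusters.values()), key=lambda c: sorted(map(str, c))
    )


def filter_clusters_by_organisms(
    clusters: Iterable[frozenset],
    organism_of: Mapping[str, str],
    min_organisms: int = 3,
) -> list:
    """Keep clusters whose members span at least ``min_organisms`` distinct organisms."""
    kept = []
    for cluster in clusters:
        unmapped = [v for v in cluster if v not in organism_of]
        if unmapped:
            raise ValueError(f"nodes without organism label: {sorted(unmapped)[:5]}")
        if len({organism_of[v] for v in cluster}) >= min_organisms:
            kept.append(cluster)
    return kept


# ---------------------------------------------------------------------------
# KEGG-ID transfer and presence/absence

def decide_kegg_transfer(
    uniprot_best_bit: Optional[float],
    kegg_best_bit: Optional[float],
    existing_kegg_id: Optional[str] = None,
    min_ratio: float = 0.8,
) -> KeggTransferDecision:
    """Transfer a KEGG ortholog ID to a family iff the best KEGG hit scores
    at least ``min_ratio`` of the best UniProt hit and no KEGG ID is already
    associated.  The threshold is inclusive."""
    if existing_kegg_id:
        return KeggTransferDecision(
            False, float(uniprot_best_bit or 0.0), kegg_best_bit, "existing KEGG id"
        )
    if kegg_best_bit is None:
        return KeggTransferDecision(
            False, float(uniprot_best_bit or 0.0), None, "no KEGG candidate"
        )
    if uniprot_best_bit is None:
        raise ValueError("missing UniProt best-hit score while evaluating a transfer")
    ok = kegg_best_bit >= min_ratio * uniprot_best_bit
    reason = "score ratio >= threshold" if ok else "score ratio below threshold"
    return KeggTransferDecision(ok, uniprot_best_bit, kegg_best_bit, reason)


def transfer_kegg_ids(table: pd.DataFrame, min_ratio: float = 0.8) -> pd.DataFrame:
    """Vector form of :func:`decide_kegg_transfer` over a family table with
    columns family, uniprot_best_bit, kegg_best_bit, existing_kegg_id."""
    rows = []
    for row in table.itertuples(index=False):
        existing = getattr(row, "existing_kegg_id", None)
        if isinstance(existing, float) and np.isnan(existing):
            existing = None
        kegg_bit = getattr(row, "kegg_best_bit", None)
        if isinstance(kegg_bit, float) and np.isnan(kegg_bit):
            kegg_bit = None
        decision = decide_kegg_transfer(
            getattr(row, "uniprot_best_bit"), kegg_bit, existing, min_ratio
        )
        rows.append(
            {
                "family": getattr(row, "family"),
                "transfer": decision.transfer,
                "uniprot_best_bit": decision.uniprot_best_bit,
                "kegg_best_bit": decision.kegg_best_bit,
                "reason": decision.reason,
            }
        )
    return pd.DataFrame(rows)


def build_presence_matrix(
    best_hits: pd.DataFrame,
    hmm_to_kegg: Mapping[str, str],
    full_evalue_cutoff: float = 1e-5,
    domain_evalue_cutoff: float = 1e-4,
) -> pd.DataFrame:
    """Genome x KEGG-ortholog 0/1 matrix from per-protein best HMM hits.

    A hit qualifies iff its full-sequence e-value <= ``full_evalue_cutoff``
    AND its best-domain e-value <= ``domain_evalue_cutoff``; a cell is 1 iff
    at least one qualifying protein maps to the KEGG id.  Expects columns
    genome, protein, hmm, full_evalue, domain_evalue.
    """
    required = {"genome", "protein", "hmm", "full_evalue", "domain_evalue"}
    missing = required - set(best_hits.columns)
    if missing:
        raise ValueError(f"best-hit table missing columns: {sorted(missing)}")
    if (best_hits["full_evalue"] < 0).any() or (best_hits["domain_evalue"] < 0).any():
        raise ValueError("e-values must be non-negative")
    genomes = sorted(best_hits["genome"].unique())
    kegg_ids = sorted(set(hmm_to_kegg.values()))
    matrix = pd.DataFrame(0, index=genomes, columns=kegg_ids, dtype=np.int8)
    qualifying = best_hits[
        (best_hits["full_evalue"] <= full_evalue_cutoff)
        & (best_hits["domain_evalue"] <= domain_evalue_cutoff)
    ]
    for row in qualifying.itertuples(index=False):
        kegg = hmm_to_kegg.get(row.hmm)
        if kegg is not None:
            matrix.at[row.genome, kegg] = 1
    return matrix


# ---------------------------------------------------------------------------
# Pipeline convenience

def run_decontamination(
    hits_by_query: Mapping[str, Sequence[HitRecord]],
    queries: Optional[Iterable[str]] = None,
    host_identity: Optional[Mapping[str, float]] = None,
    top_n: int = 10,
    evalue_cutoff: float = 1e-10,
) -> DecontamReport:
    """Run the full screen cascade: bestsum -> cellular origin -> host
    first-hit -> host identity.

    ``queries`` lists all queries including those with zero hits (defaults
    to the keys of ``hits_by_query``); ``host_identity`` maps a query to its
    best percent identity against the host proteome, when known.
    """
    if queries is None:
        queries = hits_by_query.keys()
    queries = sorted(set(queries))
    host_identity = host_identity or {}
    assignments: dict = {}
    for q in queries:
        hits = list(hits_by_query.get(q, []))
        a = assign_taxon_bestsum(hits, top_n=top_n)
        if a.species == NO_HIT:
            a = TaxonAssignment(query=q, species=NO_HIT, superkingdom=None, score=0.0)
        assignments[q] = a
    keep_cell = screen_cellular_origin(assignments.values())
    removed_cellular = {q for q, keep in keep_cell.items() if not keep}
    removed_host_first = {
        q
        for q in queries
        if q not in removed_cellular
        and not screen_host_first_hit(hits_by_query.get(q, []), evalue_cutoff)
    }
    removed_host_identity = {
        q
        for q in queries
        if q not in removed_cellular
        and q not in removed_host_first
        and not screen_host_identity(host_identity.get(q))
    }
    kept = set(queries) - removed_cellular - removed_host_first - removed_host_identity
    return DecontamReport(
        assignments=assignments,
        removed_cellular=removed_cellular,
        removed_host_first=removed_host_first,
        removed_host_identity=removed_host_identity,
        kept=kept,
    )
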