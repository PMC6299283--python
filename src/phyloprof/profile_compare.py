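"""Binary ortholog-profile comparison: Pearson/1-r, PCoA with broken-stick
assessment, Ward clustering of species and orthologs, heatmap ordering.

Profiles are species x ortholog 0/1 matrices; similarity between species is
the Pearson correlation of their binary rows (the phi coefficient), and the
species distance matrix is defined as ``D = 1 - r``.  D is generally
non-Euclidean; PCoA reports negative eigenvalues and applies no correction
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryProfileMatrix",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "PCoAResult",
    "LinkageResult",
    "build_binary_profile",
    "pearson_similarity",
    "to_dissimilarity",
    "pcoa",
    "broken_stick",
    "compare_axes_to_broken_stick",
    "ward_cluster",
    "cut_clusters",
    "heatmap_layout",
]


@dataclass
class BinaryProfileMatrix:
    species: list
    orthologs: list
    values: np.ndarray
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.species), len(self.orthologs)):
            raise ValueError("values shape does not match labels")
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("profile values must be 0/1")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if len(set(self.orthologs)) != len(self.orthologs):
            raise ValueError("duplicate ortholog ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.orthologs)


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    species: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity diagonal must be 1")


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    species: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 2 + 1e-12):
            raise ValueError("1-r dissimilarities must lie in [0, 2]")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("dissimilarity diagonal must be 0")


@dataclass
class PCoAResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``eigenvalues`` is the full spectrum (descending, may contain negative
    values); ``explained`` covers positive axes only and sums to 1;
    ``broken_stick`` gives the null expectation per positive axis.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    broken_stick: np.ndarray
    species: list
    n_positive: int


@dataclass
class LinkageResult:
    """Agglomerative merge history (cluster_a, cluster_b, height, size).

    Original observations are clusters ``0..n-1``; the merge at step ``i``
    creates cluster ``n + i`` (the scipy convention).  ``leaf_order`` is the
    dendrogram leaf sequence from a left-before-right traversal.
    """

    merges: list
    leaf_order: list
    n: int
    labels: Optional[list] = None

    def __post_init__(self) -> None:
        if len(self.merges) != self.n - 1:
            raise ValueError(f"expected {self.n - 1} merges, got {len(self.merges)}")

    @property
    def heights(self) -> list:
        return [m[2] for m in self.merges]


# ---------------------------------------------------------------------------

def build_binary_profile(counts, drop_empty: bool = True) -> BinaryProfileMatrix:
    """Binarize a species x ortholog count table: 1 iff count >= 1.

    With ``drop_empty``, orthologs absent from every species are removed and
    reported in ``dropped``.
    """
    if isinstance(counts, pd.DataFrame):
        species = list(counts.index)
        orthologs = list(counts.columns)
        values = counts.to_numpy()
    else:
        values = np.asarray(counts)
        species = [f"s{i + 1}" for i in range(values.shape[0])]
        orthologs = [f"og{j + 1}" for j in range(values.shape[1])]
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    binary = (values >= 1).astype(np.int8)
    dropped: list = []
    if drop_empty:
        empty = binary.sum(axis=0) == 0
        dropped = [o for o, e in zip(orthologs, empty) if e]
        if dropped:
            binary = binary[:, ~empty]
            orthologs = [o for o, e in zip(orthologs, empty) if not e]
    return BinaryProfileMatrix(
        species=species, orthologs=orthologs, values=binary, dropped=dropped
    )


def pearson_similarity(profile: BinaryProfileMatrix) -> SimilarityMatrix:
    """Pairwise Pearson r between species' 0/1 rows (the phi coefficient)."""
    X = profile.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species")
    sd = X.std(axis=1)
    constant = [s for s, v in zip(profile.species, sd) if v == 0]
    if constant:
        raise ValueError(
            f"constant presence/absence rows (r undefined): {constant}"
        )
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(values=r, species=list(profile.species))


def to_dissimilarity(sim: SimilarityMatrix) -> DissimilarityMatrix:
    """Complementary distance D = 1 - r (zero diagonal, range [0, 2])."""
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=d, species=list(sim.species))


def _as_square(D, labels=None):
    if isinstance(D, DissimilarityMatrix):
        return np.asarray(D.values, dtype=float), list(D.species)
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square matrix")
    if labels is None:
        labels = list(range(arr.shape[0]))
    return arr, list(labels)


def pcoa(D, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling by Gower double-centering.

    Eigendecomposes ``-1/2 J D^2 J``; coordinates are eigenvectors scaled by
    the square root of their (positive) eigenvalues for the top ``k`` axes.
    Negative eigenvalues are reported unchanged; explained fractions
    normalize over positive eigenvalues only.
    """
    arr, labels = _as_square(D)
    if not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(arr < 0):
        raise ValueError("dissimilarity matrix must be non-negative")
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (arr ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    n_pos = int(np.sum(eigval > tol))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive axes available (requested {k})", stacklevel=2
        )
    k_eff = min(k, n_pos)
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    pos_sum = eigval[:n_pos].sum() if n_pos else 1.0
    explained = eigval[:n_pos] / pos_sum
    bs = broken_stick(n_pos) if n_pos else np.array([])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigval,
        explained=explained,
        broken_stick=bs,
        species=labels,
        n_positive=n_pos,
    )


def broken_stick(n_axes: int) -> np.ndarray:
    """Broken-stick null fractions E_i = (1/n) * sum_{j=i..n} 1/j."""
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    inv = 1.0 / np.arange(1, n_axes + 1)
    return np.cumsum(inv[::-1])[::-1] / n_axes


def compare_axes_to_broken_stick(result: PCoAResult, n_axes: int = 2) -> list:
    """Per-axis verdicts: does the explained fraction strictly exceed the
    broken-stick expectation?  Returns (axis, explained, expected, exceeds)."""
    if result.n_positive < n_axes:
        raise ValueError(
            f"only {result.n_positive} positive axes, cannot assess {n_axes}"
        )
    out = []
    for i in range(n_axes):
        expl = float(result.explained[i])
        expect = float(result.broken_stick[i])
        out.append((i + 1, expl, expect, expl > expect))
    return out


# ---------------------------------------------------------------------------
# Ward clustering (Lance-Williams)

def ward_cluster(D, variant: str = "ward2", labels=None) -> LinkageResult:
    """Agglomerative Ward clustering of a distance matrix.

    ``ward2`` (default) applies the Lance-Williams Ward update to squared
    distances and reports square-rooted heights; ``ward1`` applies it to the
    distances as given.  Ties are broken by the smallest (id_a, id_b) pair;
    leaf order comes from a left-before-right traversal of the merge tree.
    """
    if variant not in ("ward1", "ward2"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    arr, labels = _as_square(D, labels)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.allclose(arr, arr.T) or np.any(arr < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    W = arr.astype(float) ** 2 if variant == "ward2" else arr.astype(float).copy()

    dist: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = W[i, j]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list = []
    children: dict = {}
    next_id = n
    for _ in range(n - 1):
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                v = dist[(a, b) if a < b else (b, a)]
                if best is None or v < best:
                    best = v
                    best_pair = (min(a, b), max(a, b))
        a, b = best_pair
        height = float(np.sqrt(best)) if variant == "ward2" else float(best)
        na, nb = sizes[a], sizes[b]
        merges.append((a, b, height, na + nb))
        children[next_id] = (a, b)
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = dist[(a, c) if a < c else (c, a)]
            dbc = dist[(b, c) if b < c else (c, b)]
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * best) / (na + nb + nc)
            dist[(c, next_id)] = new
        active = [c for c in active if c not in (a, b)] + [next_id]
        sizes[next_id] = na + nb
        next_id += 1

    def _leaves(node: int) -> list:
        if node < n:
            return [node]
        a, b = children[node]
        return _leaves(a) + _leaves(b)

    leaf_order = _leaves(next_id - 1)
    return LinkageResult(merges=merges, leaf_order=leaf_order, n=n, labels=labels)


def cut_clusters(linkage: LinkageResult, k: int) -> np.ndarray:
    """Flat cluster labels (0..k-1, ordered by first occurrence) from the
    first ``n - k`` merges of the linkage."""
    n = linkage.n
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _, _) in enumerate(linkage.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    labels = np.empty(n, dtype=int)
    seen: dict = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen)
        labels[i] = seen[root]
    return labels


def heatmap_layout(
    profile: BinaryProfileMatrix,
    species_linkage: LinkageResult,
    ortholog_linkage: Optional[LinkageResult] = None,
    clamp: Optional[tuple] = None,
):
    """Reorder a profile (or similarity) matrix by dendrogram leaf orders.

    Values are never mutated; ``clamp`` (e.g. ``(0, 1)`` for a similarity
    display) is returned as display metadata only.  Returns
    ``(ordered DataFrame, row_order, col_order, clamp)``.
    """
    df = profile.to_frame() if isinstance(profile, BinaryProfileMatrix) else profile
    if species_linkage.n != df.shape[0]:
        raise ValueError("species linkage does not match matrix rows")
    row_order = list(species_linkage.leaf_order)
    if ortholog_linkage is not None:
        if ortholog_linkage.n != df.shape[1]:
            raise ValueError("ortholog linkage does not match matrix columns")
        col_order = list(ortholog_linkage.leaf_order)
    else:
        col_order = list(range(df.shape[1]))
    ordered = df.iloc[row_order, col_order]
    return ordered, row_order, col_order, clamp
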