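"""Progressive removal of the fastest-evolving alignment columns.

Columns are ranked once, on the full alignment's per-site relative rates
(descending rate, ties broken by ascending column index), and nested subsets
are produced by removing the top ``round_half_up(f * L)`` columns for each
fraction ``f`` of the plan.  The default plan (5% steps up to 95%) yields
19 subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio_trees import Alignment

__all__ = [
    "SiteRates",
    "StripPlan",
    "read_site_rates",
    "rank_sites_by_rate",
    "strip_fastest",
    "progressive_strip",
]


@dataclass
class SiteRates:
    """Per-column relative evolutionary rates (mean ~ 1)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1 or self.rates.size == 0:
            raise ValueError("rates must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("rates must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.rates.size)


@dataclass
class StripPlan:
    """Fractions of fastest sites to remove, ``step, 2*step, ... <= max_fraction``."""

    step: float = 0.05
    max_fraction: float = 0.95
    fractions: list = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.max_fraction < 1):
            raise ValueError(
                f"require 0 < step <= max_fraction < 1, got step={self.step}, "
                f"max_fraction={self.max_fraction}"
            )
        fractions = []
        i = 1
        while True:
            f = round(i * self.step, 12)
            if f > self.max_fraction + 1e-12:
                break
            fractions.append(min(f, self.max_fraction))
            i += 1
        self.fractions = fractions


def read_site_rates(path) -> SiteRates:
    """Read an IQ-TREE ``-wsr``-style rate table.

    Expects a TSV with a header line; ``#`` comment lines are ignored.
    Accepts both (Site, Rate) and (Site, Rate, Cat[, ...]) layouts.  Rows
    may be out of order; the result is sorted by 1-based site index, and
    missing or duplicate site indices are an error.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=0)
    cols = {c.lower(): c for c in df.columns}
    site_col = cols.get("site")
    rate_col = cols.get("rate")
    if site_col is None or rate_col is None:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need at least Site and Rate columns")
        site_col, rate_col = df.columns[0], df.columns[1]
    sites = pd.to_numeric(df[site_col], errors="coerce")
    rates = pd.to_numeric(df[rate_col], errors="coerce")
    if sites.isna().any():
        line = int(sites.index[sites.isna()][0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric site index at line {line}")
    if rates.isna().any():
        line = int(rates.index[rates.isna()][0]) + 2
        raise ValueError(f"{path}: non-numeric rate at line {line}")
    sites = sites.astype(int)
    if sites.duplicated().any():
        dup = int(sites[sites.duplicated()].iloc[0])
        raise ValueError(f"{path}: duplicate site index {dup}")
    order = np.argsort(sites.to_numpy(), kind="stable")
    sorted_sites = sites.to_numpy()[order]
    expected = np.arange(1, len(sorted_sites) + 1)
    if not np.array_equal(sorted_sites, expected):
        missing = sorted(set(expected) - set(sorted_sites))
        raise ValueError(f"{path}: missing site indices {missing[:5]}")
    return SiteRates(rates.to_numpy()[order])


def rank_sites_by_rate(rates: SiteRates) -> np.ndarray:
    """Column indices ordered fastest-first; ties by ascending column index."""
    r = rates.rates
    # lexsort: last key is primary
    return np.lexsort((np.arange(len(r)), -r))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def strip_fastest(aln: Alignment, rates: SiteRates, fraction: float) -> Alignment:
    """Remove the ``round_half_up(fraction * L)`` fastest columns.

    Retained columns keep their original relative order.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if len(rates) != aln.length:
        raise ValueError(
            f"rates length {len(rates)} != alignment length {aln.length}"
        )
    L = aln.length
    k = _round_half_up(fraction * L)
    if k == 0:
        return aln
    removed = set(rank_sites_by_rate(rates)[:k].tolist())
    keep = [i for i in range(L) if i not in removed]
    return aln.select_columns(keep)


def progressive_strip(
    aln: Alignment, rates: SiteRates, plan: StripPlan | None = None
) -> list:
    """One stripped alignment per plan fraction, nested along the plan.

    Returns an ordered list of ``(fraction, Alignment)`` pairs; the default
    plan yields 19 subsets.
    """
    if plan is None:
        plan = StripPlan()
    return [(f, strip_fastest(aln, rates, f)) for f in plan.fractions]
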