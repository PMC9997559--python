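"""Strict-clock calibration and per-generation mutation-rate conversion.

The substitution rate of a parasite lineage can be calibrated in
*years* from a dated host split, but comparisons with experimental
mutation-accumulation estimates require a rate per *generation*.  This
module holds the pieces of that conversion chain:

* a shifted (offset) log-normal node-age prior, as used for fossil
  calibration of the deepest within-species split;
* extraction of 4-fold degenerate alignment columns, the
  approximately neutral marker set used for clock analyses;
* pairwise p- and JC69 distances on those columns, and a strict-clock
  rate ``d / (2 T)`` from a mean between-clade distance and a split
  time;
* life-cycle bookkeeping (generation time in hours, dormant months per
  year) converting a per-year rate into a per-generation rate.

The year is taken as 365 days and a month as a twelfth of a year.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ShiftedLogNormal",
    "LifeCycleParams",
    "ClockEstimate",
    "fourfold_degenerate_columns",
    "pairwise_distance",
    "strict_clock_rate",
    "generations_per_year",
    "per_generation_rate",
]

#: third-position 4-fold degenerate codon families, keyed by the first
#: two codon bases (standard genetic code)
FOURFOLD_PREFIXES = frozenset(
    ["TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"]
)


@dataclass(frozen=True)
class ShiftedLogNormal:
    """Log-normal distribution translated by ``offset``.

    ``M`` and ``S`` are the mean and standard deviation of the
    underlying normal (log space); ``offset`` shifts the support and is
    in the units of the calibrated variable (here million years).
    """

    M: float
    S: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("S must be > 0")

    def median(self) -> float:
        return self.offset + math.exp(self.M)

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile probability must be in (0, 1), got {q}")
        return self.offset + math.exp(self.M + norm.ppf(q) * self.S)

    def interval(self, lo: float = 0.05, hi: float = 0.95) -> tuple[float, float]:
        return self.quantile(lo), self.quantile(hi)


@dataclass(frozen=True)
class LifeCycleParams:
    """Generation time and seasonal dormancy of the parasite.

    ``generation_time_h`` is the doubling/replication time in hours;
    ``resting_months`` counts months per year spent as a dormant spore
    without replication (0 for a fully active year); ``year_days`` is
    the calendar convention (365 by default).
    """

    generation_time_h: float = 63.0
    resting_months: float = 0.0
    year_days: float = 365.0

    def __post_init__(self) -> None:
        if self.generation_time_h <= 0:
            raise ValueError("generation time must be > 0")
        if not 0 <= self.resting_months < 12:
            raise ValueError("resting months must be in [0, 12)")


@dataclass(frozen=True)
class ClockEstimate:
    """A clock rate (per site per year) with its per-generation conversion."""

    rate_per_year: float
    rate_bounds: tuple[float, float] | None
    split_time_years: float
    life_cycle: LifeCycleParams
    mu_per_generation: float = field(init=False)
    mu_bounds: tuple[float, float] | None = field(init=False)

    def __post_init__(self) -> None:
        g = generations_per_year(self.life_cycle)
        object.__setattr__(self, "mu_per_generation", self.rate_per_year / g)
        if self.rate_bounds is not None:
            lo, hi = self.rate_bounds
            if not lo <= self.rate_per_year <= hi:
                raise ValueError("rate bounds must bracket the point estimate")
            object.__setattr__(self, "mu_bounds", (lo / g, hi / g))
        else:
            object.__setattr__(self, "mu_bounds", None)


def fourfold_degenerate_columns(codon_alignment) -> list[int]:
    """Alignment columns (0-based) that are 4-fold degenerate in every sequence.

    A third codon position is kept only if, in *every* sequence, the
    first two bases of its codon define a 4-fold family and the codon
    contains no gap or ambiguous base.  Masked columns (when the
    alignment carries a mask) disqualify their codon.
    """
    seqs = codon_alignment.sequences_list()
    mask = getattr(codon_alignment, "column_mask", None)
    length = len(seqs[0])
    kept: list[int] = []
    for start in range(0, length - length % 3, 3):
        if mask is not None and mask[start : start + 3].any():
            continue
        ok = True
        for s in seqs:
            codon = s[start : start + 3].upper()
            if any(b not in "ACGT" for b in codon):
                ok = False
                break
            if codon[:2] not in FOURFOLD_PREFIXES:
                ok = False
                break
        if ok:
            kept.append(start + 2)
    return kept


def pairwise_distance(sequences: dict[str, str]) -> "pd.DataFrame":
    """Pairwise p-distance and JC69 distance over shared ungapped columns.

    ``sequences`` maps sample id to an equal-length (typically
    concatenated 4-fold site) string.  JC69 is
    ``-(3/4) ln(1 - 4p/3)``; it is undefined (NaN, flagged) when
    ``p >= 0.75``.
    """
    import pandas as pd

    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    if lengths == {0}:
        raise ValueError("need at least 1 column")
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    arr = {n: np.frombuffer(sequences[n].upper().encode(), dtype="S1") for n in names}
    valid = {n: np.isin(arr[n], bases) for n in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        shared = valid[a] & valid[b]
        n_shared = int(shared.sum())
        if n_shared == 0:
            rows.append((a, b, np.nan, np.nan, 0, True))
            continue
        p = float((arr[a][shared] != arr[b][shared]).sum()) / n_shared
        if p >= 0.75:
            jc, flagged = np.nan, True
        else:
            jc, flagged = -0.75 * math.log1p(-4.0 * p / 3.0), False
        rows.append((a, b, p, jc, n_shared, flagged))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "p_distance", "jc69", "n_sites", "jc69_undefined"]
    )


def strict_clock_rate(mean_distance: float, split_time_years: float) -> float:
    """Substitutions per site per year from a between-clade distance.

    Two clades separated ``T`` years ago have accumulated ``2 T r``
    substitutions per site along the two branches, so ``r = d / (2 T)``.
    """
    if split_time_years <= 0:
        raise ValueError("split time must be > 0")
    if mean_distance < 0:
        raise ValueError("distance must be >= 0")
    return mean_distance / (2.0 * split_time_years)


def generations_per_year(params: LifeCycleParams) -> float:
    """Number of generations completed in one calendar year.

    Dormant months are removed from the active season before dividing
    by the generation time.
    """
    active_days = params.year_days * (12.0 - params.resting_months) / 12.0
    return active_days * 24.0 / params.generation_time_h


def per_generation_rate(rate_per_year: float, params: LifeCycleParams) -> float:
    """Convert a per-year substitution rate to a per-generation mutation rate."""
    if rate_per_year < 0:
        raise ValueError("rate must be >= 0")
    return rate_per_year / generations_per_year(params)
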