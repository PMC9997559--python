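"""Ploidy diagnosis from allele balance and k-mer spectra.

A haploid sample has no heterozygous sites: at biallelic positions the
reads overwhelmingly support a single allele (minor-read fractions near
0, inflated only by sequencing error), and its k-mer frequency
spectrum has a single mode at the sequencing coverage.  A diploid
sample shows a heterozygous band of minor-read fractions around 0.5
and a secondary spectrum mode at half coverage.  Both evidence sources
are computed independently and combined conservatively: when they
disagree, or when too few informative sites exist (the low-polymorphism
regime where haploidy cannot be distinguished from, e.g., mixed
infection), the verdict is ``ambiguous`` rather than a forced call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PloidyCall",
    "allele_balance_histogram",
    "count_kmers",
    "detect_spectrum_peaks",
    "call_ploidy",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# decision thresholds (the qualitative criteria made explicit)
HET_BAND = (0.35, 0.65)  # minor-read fraction range counted as heterozygous
HAPLOID_MAX_BAND_MASS = 0.05
DIPLOID_MIN_BAND_MASS = 0.20
HALF_PEAK_RANGE = (0.35, 0.65)  # secondary/main peak location ratio
MIN_INFORMATIVE_SITES = 100


@dataclass(frozen=True)
class PloidyCall:
    sample: str
    verdict: str  # haploid | diploid | ambiguous
    band_mass: float
    n_informative: int
    peaks: tuple[int, ...] = field(default=())


def allele_balance_histogram(
    support: pd.DataFrame,
    sample: str,
    min_depth: int = 10,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of minor-allele read fractions at biallelic sites.

    ``support`` has columns sample, chrom, pos, depth, alt_count.
    Sites below ``min_depth`` (and zero-depth sites) are excluded.
    Returns (counts, bin edges, number of qualifying sites); an empty
    histogram (0 sites) is a flag, not an error.
    """
    rows = support[(support["sample"] == sample) & (support["depth"] >= max(min_depth, 1))]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if len(rows) == 0:
        return np.zeros(len(edges) - 1, dtype=int), edges, 0
    depth = rows["depth"].to_numpy(dtype=float)
    alt = rows["alt_count"].to_numpy(dtype=float)
    minor = np.minimum(alt, depth - alt) / depth
    counts, _ = np.histogram(minor, bins=edges)
    return counts, edges, len(rows)


def canonical_kmer(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return min(kmer, rc)


def count_kmers(sequences, k: int) -> Counter:
    """Canonical k-mer multiplicity histogram.

    Counts each canonical k-mer (lexicographic minimum of the k-mer and
    its reverse complement) across all input sequences, then returns a
    histogram mapping multiplicity -> number of distinct k-mers.
    Windows containing non-ACGT characters are skipped; sequences
    shorter than k contribute nothing.
    """
    if not 1 < k <= 31:
        raise ValueError("k must be in (1, 31]")
    counts: Counter = Counter()
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if any(b not in "ACGT" for b in kmer):
                continue
            counts[canonical_kmer(kmer)] += 1
    return Counter(counts.values())


def detect_spectrum_peaks(
    histogram: Counter | dict[int, int],
    smoothing_window: int = 3,
    min_multiplicity: int = 3,
    min_height_frac: float = 0.05,
    min_prominence_frac: float = 0.02,
) -> list[int]:
    """Locate modes of a k-mer multiplicity spectrum.

    The spectrum is moving-average smoothed, the low-multiplicity
    region (< ``min_multiplicity``, dominated by sequencing-error
    k-mers) ignored, and local maxima kept if they reach 5% of the
    highest peak; a small prominence floor suppresses shoulder noise.
    """
    if not histogram:
        raise ValueError("empty k-mer histogram")
    max_mult = max(histogram)
    dense = np.zeros(max_mult + 1, dtype=float)
    for mult, n in histogram.items():
        dense[mult] = n
    dense[: min(min_multiplicity, len(dense))] = 0.0
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        smooth = np.convolve(dense, kernel, mode="same")
    else:
        smooth = dense
    if smooth.max() <= 0:
        return []
    # a genuine coverage mode is locally curved; wide flat plateaus
    # (e.g. a uniform spectrum) are not modes
    idx, props = find_peaks(
        smooth, prominence=min_prominence_frac * smooth.max(), plateau_size=(1, 5)
    )
    if len(idx) == 0:
        return []
    heights = smooth[idx]
    keep = heights >= min_height_frac * heights.max()
    return [int(i) for i in idx[keep]]


def call_ploidy(
    ab_histogram: tuple[np.ndarray, np.ndarray, int],
    peaks: list[int] | None,
    sample: str = "",
    min_informative: int = MIN_INFORMATIVE_SITES,
) -> PloidyCall:
    """Combine allele-balance and spectrum evidence into a verdict.

    Haploid: heterozygous-band mass below 5% and no spectrum mode near
    half the main mode.  Diploid: band mass at least 20% or a
    half-coverage mode.  Anything else — including fewer informative
    sites than ``min_informative`` and outright conflict between the
    two evidence sources — is ambiguous.
    """
    counts, edges, n_sites = ab_histogram
    total = counts.sum()
    if total > 0:
        centers = (edges[:-1] + edges[1:]) / 2
        band = (centers >= HET_BAND[0]) & (centers < HET_BAND[1])
        band_mass = float(counts[band].sum() / total)
    else:
        band_mass = float("nan")
    half_peak = False
    if peaks:
        main = max(peaks, key=lambda p: p)  # highest-multiplicity mode = full coverage
        half_peak = any(
            HALF_PEAK_RANGE[0] * main <= p <= HALF_PEAK_RANGE[1] * main
            for p in peaks
            if p != main
        )
    peaks_t = tuple(sorted(peaks)) if peaks else ()

    if n_sites < min_informative or total == 0:
        verdict = "ambiguous"
    elif band_mass < HAPLOID_MAX_BAND_MASS and half_peak:
        verdict = "ambiguous"  # histogram haploid, spectrum diploid
    elif band_mass >= DIPLOID_MIN_BAND_MASS and peaks and not half_peak and len(peaks) == 1:
        verdict = "ambiguous"  # histogram diploid, spectrum haploid
    elif band_mass < HAPLOID_MAX_BAND_MASS and not half_peak:
        verdict = "haploid"
    elif band_mass >= DIPLOID_MIN_BAND_MASS or half_peak:
        verdict = "diploid"
    else:
        verdict = "ambiguous"
    return PloidyCall(sample, verdict, band_mass, n_sites, peaks_t)
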