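"""Missing-data-aware windowed nucleotide diversity.

π here is the ratio-of-sums estimator over an *all-sites* matrix: per
site, the number of discordant unordered sample pairs ``D_s`` and the
number of genotyped unordered pairs ``C_s = n_s (n_s - 1) / 2``;
window π = ΣD_s / ΣC_s.  Invariant sites contribute only to the
denominator and missing calls simply drop out of both sums, which is
what keeps the estimator unbiased under arbitrary missingness (unlike
a mean of per-site ratios or a SNP-only estimate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import MISSING, SiteMatrix, _allele_counts

__all__ = ["depth_filter", "windowed_pi", "flag_outlier_windows", "site_pair_counts"]


def depth_filter(
    sites: SiteMatrix,
    metadata: pd.DataFrame,
    low: float = 0.5,
    high: float = 2.0,
) -> SiteMatrix:
    """Mask genotype calls with outlying read depth.

    A call whose depth is below ``low`` x or above ``high`` x the
    sample's mean whole-genome depth is set to missing (never deleted:
    the site stays in the matrix so denominators remain correct).  Site
    classes are implicitly recomputed downstream — a SNP whose
    alternate calls are all masked becomes invariant.
    """
    absent = [s for s in sites.samples if s not in metadata.index]
    if absent:
        raise ValueError(f"no mean depth in metadata for samples: {absent}")
    means = metadata.loc[sites.samples, "mean_depth"].to_numpy(dtype=float)
    bad = (sites.depth < low * means) | (sites.depth > high * means)
    alleles = sites.alleles.copy()
    alleles[bad] = MISSING
    out = SiteMatrix(
        chrom_names=sites.chrom_names,
        chrom_lengths=sites.chrom_lengths,
        chrom_index=sites.chrom_index,
        pos=sites.pos,
        samples=list(sites.samples),
        ref=sites.ref,
        alleles=alleles,
        depth=sites.depth.copy(),
    )
    return out


def site_pair_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site discordant (D_s) and genotyped (C_s) unordered pair counts.

    Multiallelic sites are handled naturally: with ``c_a`` copies of
    allele ``a`` among ``n_s`` genotyped calls,
    ``D_s = C_s − Σ_a c_a (c_a − 1) / 2``.
    """
    counts = _allele_counts(alleles)
    n = counts.sum(axis=1)
    C = n * (n - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=1)
    return (C - same).astype(np.int64), C.astype(np.int64)


def windowed_pi(
    sites: SiteMatrix,
    samples: list[str] | None = None,
    window: int = 1000,
    lineage: str = "",
) -> pd.DataFrame:
    """Tile each chromosome with fixed windows and compute π per window.

    Windows are anchored at position 0; the trailing partial window is
    kept with its true span.  A window in which no site has two or more
    genotyped samples has an undefined π (NaN) and is excluded from any
    percentile ranking.

    Returns a table with columns chrom, start, end, n_diffs,
    n_comparisons, pi, lineage, flag.
    """
    if samples is not None:
        if len(samples) < 2:
            raise ValueError("need at least 2 samples for pairwise diversity")
        sub = sites.alleles[:, sites.sample_index(samples)]
    else:
        if sites.n_samples < 2:
            raise ValueError("need at least 2 samples for pairwise diversity")
        sub = sites.alleles
    D, C = site_pair_counts(sub)

    rows = []
    for c, (name, length) in enumerate(zip(sites.chrom_names, sites.chrom_lengths)):
        idx = np.flatnonzero(sites.chrom_index == c)
        pos = sites.pos[idx]
        wbin = pos // window
        n_windows = max(int(np.ceil(length / window)), 1)
        d_sum = np.bincount(wbin, weights=D[idx], minlength=n_windows)
        c_sum = np.bincount(wbin, weights=C[idx], minlength=n_windows)
        for w in range(n_windows):
            start = w * window
            end = min(start + window, length)
            Cw = int(c_sum[w])
            rows.append(
                (
                    name,
                    start,
                    end,
                    int(d_sum[w]),
                    Cw,
                    d_sum[w] / Cw if Cw > 0 else np.nan,
                )
            )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_diffs", "n_comparisons", "pi"]
    )
    table["lineage"] = lineage
    table["flag"] = "none"
    table["hgt_overlap"] = False
    return table


def flag_outlier_windows(
    table: pd.DataFrame,
    percentiles: tuple[float, float] = (95.0, 99.0),
    hgt_regions: list[tuple[str, int, int]] | None = None,
    min_windows: int = 20,
) -> pd.DataFrame:
    """Flag windows above empirical π percentiles; annotate HGT overlap.

    Thresholds are linear-interpolation percentiles of the *defined*
    windows; a window is flagged only if its π is strictly greater than
    the threshold (so an all-equal table gets no flags), and the higher
    percentile flag wins.  Windows overlapping any region of the mask
    BED (e.g. host-to-parasite HGT segments, where host-read
    mis-mapping inflates apparent diversity) carry an extra boolean.
    """
    defined = table["pi"].notna()
    if defined.sum() < min_windows:
        raise ValueError(
            f"only {int(defined.sum())} defined windows; need >= {min_windows}"
        )
    lo_p, hi_p = sorted(percentiles)
    pis = table.loc[defined, "pi"].to_numpy()
    lo_t = np.percentile(pis, lo_p)  # linear interpolation (default)
    hi_t = np.percentile(pis, hi_p)
    out = table.copy()
    out["flag"] = "none"
    out.loc[defined & (out["pi"] > lo_t), "flag"] = f"p{lo_p:g}"
    out.loc[defined & (out["pi"] > hi_t), "flag"] = f"p{hi_p:g}"
    out["hgt_overlap"] = False
    if hgt_regions:
        for chrom, start, end in hgt_regions:
            hit = (out["chrom"] == chrom) & (out["start"] < end) & (out["end"] > start)
            out.loc[hit, "hgt_overlap"] = True
    out.attrs["thresholds"] = {f"p{lo_p:g}": float(lo_t), f"p{hi_p:g}": float(hi_t)}
    return out
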