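"""Coding-sequence diversity and selection-efficacy statistics.

Per gene, nonsynonymous and synonymous per-site diversity (π_N, π_S)
are computed with unweighted Nei–Gojobori (1986) site counting and
minimal-mutational-pathway difference counting, with invariant codons
in the denominators.  A low π_N/π_S marks efficient purifying
selection; comparing a conserved focal gene set (BUSCO-like) against
the genomic background measures selection efficacy genome-wide.  The
McDonald–Kreitman test and its asymptotic extension contrast
polymorphism with outgroup divergence to estimate the adaptive
substitution fraction α.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats
from scipy.optimize import curve_fit

from .io_formats import GeneModel, SiteMatrix, apply_variants_to_reference, extract_cds

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "GeneDiversity",
    "MKTResult",
    "mask_divergent_regions",
    "ng86_site_counts",
    "codon_path_diffs",
    "gene_pi_n_s",
    "compare_gene_sets",
    "mkt_alpha",
    "asymptotic_alpha",
    "mkt_counts",
    "build_codon_alignments",
]

_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Codon-aligned per-sample CDS sequences for one gene.

    Sequences are equal length, length divisible by 3; missing data is
    encoded as ``N``.  ``column_mask`` marks columns excluded from all
    counts (e.g. by the divergence-masking rule).  ``outgroup`` names
    the outgroup sequence, if present, for divergence-based tests.
    """

    gene_id: str
    sequences: dict[str, str]
    column_mask: np.ndarray | None = None
    gene_set: str = "background"
    outgroup: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")
        if self.column_mask is None:
            self.column_mask = np.zeros(self.length, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if len(self.column_mask) != self.length:
                raise ValueError(f"{self.gene_id}: mask length mismatch")

    def sequences_list(self) -> list[str]:
        return list(self.sequences.values())

    def ingroup_ids(self) -> list[str]:
        return [s for s in self.sequences if s != self.outgroup]


@dataclass(frozen=True)
class GeneDiversity:
    gene_id: str
    gene_set: str
    n_sites: float
    s_sites: float
    pi_n: float
    pi_s: float
    n_codons_used: int

    @property
    def ratio(self) -> float:
        """π_N/π_S; NaN when π_S = 0 (excluded from medians)."""
        if self.pi_s > 0:
            return self.pi_n / self.pi_s
        return float("nan")


@dataclass
class MKTResult:
    Pn: float
    Ps: float
    Dn: float
    Ds: float
    alpha: float = field(default=float("nan"))
    alpha_undefined: bool = False
    p_value: float = field(default=float("nan"))
    # asymptotic extension
    bin_x: np.ndarray | None = None
    bin_alpha: np.ndarray | None = None
    fit_a: float = float("nan")
    fit_b: float = float("nan")
    fit_c: float = float("nan")
    alpha_asymptotic: float = float("nan")
    linear_fallback: bool = False


# ---------------------------------------------------------------------------
# alignment masking


def mask_divergent_regions(
    seq_a: str,
    seq_b: str,
    threshold: float = 0.005,
    window: int = 100,
    step: int = 50,
) -> np.ndarray:
    """Mask alignment windows where two reference sequences diverge excessively.

    Sliding windows (gaps excluded from the denominator) whose pairwise
    difference fraction is *strictly* greater than ``threshold``
    (default 0.5%) are masked; such regions are treated as poorly
    aligned or non-orthologous and the mask is propagated to the
    multi-sample alignment downstream.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = len(seq_a)
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid = np.isin(a, bases) & np.isin(b, bases)
    diff = valid & (a != b)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    starts = range(0, n, step) if window < n else [0]
    for s in starts:
        e = min(s + window, n)
        denom = int(valid[s:e].sum())
        if denom and diff[s:e].sum() / denom > threshold:
            mask[s:e] = True
        if e == n:
            break
    return mask


# ---------------------------------------------------------------------------
# Nei–Gojobori counting


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Unweighted NG86 (N_sites, S_sites) for one codon.

    Each of the nine single-base neighbours is classified; the
    synonymous fraction at each position contributes to S, and
    N = 3 − S.  Changes *to* a stop codon count as nonsynonymous.
    Stop codons are not valid input.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _CODON_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons.

    Averaged over all minimal mutational pathways that do not pass
    through a stop codon; if every pathway does, all changes count as
    nonsynonymous (standard NG86 practice, deterministic).
    """
    c1, c2 = c1.upper(), c2.upper()
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    path_counts: list[tuple[float, float]] = []
    for order in itertools.permutations(pos):
        cur = c1
        nd = sd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            path_counts.append((nd, sd))
    if not path_counts:
        return float(len(pos)), 0.0
    n = sum(p[0] for p in path_counts) / len(path_counts)
    s = sum(p[1] for p in path_counts) / len(path_counts)
    return n, s


_VALID_CODONS = np.array(
    sorted(c.encode() for c in _CODON_AA if _CODON_AA[c] != "*"), dtype="S3"
)


def _usable_codons(cods: np.ndarray) -> np.ndarray:
    """Boolean mask of codons over ACGT that are not stops."""
    return np.isin(cods, _VALID_CODONS)


def _codon_ok(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in _BASES for b in codon)
        and codon not in STOP_CODONS
    )


def gene_pi_n_s(alignment: CodonAlignment, ingroup: list[str] | None = None) -> GeneDiversity:
    """π_N and π_S for one gene over all unordered ingroup pairs.

    Site counts are NG86 fractions averaged over sequences; pairwise
    differences are pathway-averaged.  Codons that are masked, contain
    ambiguity, or are stops are skipped (they contribute no sites for
    that sequence/pair).  A gene with every codon masked yields NaN
    diversities, flagged by ``n_codons_used == 0``.
    """
    ids = ingroup if ingroup is not None else alignment.ingroup_ids()
    if len(ids) < 2:
        raise ValueError("need at least 2 ingroup sequences")
    mask = alignment.column_mask.reshape(-1, 3).any(axis=1)
    codon_idx = np.flatnonzero(~mask)
    # codon-wise byte views for fast comparison
    cods = {
        i: np.frombuffer(alignment.sequences[i].upper().encode(), dtype="S3")
        for i in ids
    }
    usable = {i: _usable_codons(cods[i]) & ~mask for i in ids}

    # per-sequence NG86 site totals over usable codons
    n_site_sums, s_site_sums = [], []
    for i in ids:
        vals, counts = np.unique(cods[i][usable[i]], return_counts=True)
        n_tot = s_tot = 0.0
        for v, c in zip(vals, counts):
            n, s = ng86_site_counts(v.decode())
            n_tot += c * n
            s_tot += c * s
        n_site_sums.append(n_tot)
        s_site_sums.append(s_tot)
    n_sites = float(np.mean(n_site_sums))
    s_sites = float(np.mean(s_site_sums))

    nd_sum = sd_sum = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(ids, 2):
        both = usable[a] & usable[b]
        for k in np.flatnonzero((cods[a] != cods[b]) & both):
            dn, ds = codon_path_diffs(cods[a][k].decode(), cods[b][k].decode())
            nd_sum += dn
            sd_sum += ds
        n_pairs += 1

    if len(codon_idx) == 0 or (n_sites == 0 and s_sites == 0):
        return GeneDiversity(
            alignment.gene_id, alignment.gene_set, 0.0, 0.0, float("nan"), float("nan"), 0
        )
    pi_n = (nd_sum / n_pairs) / n_sites if n_sites > 0 else float("nan")
    pi_s = (sd_sum / n_pairs) / s_sites if s_sites > 0 else float("nan")
    return GeneDiversity(
        alignment.gene_id, alignment.gene_set, n_sites, s_sites, pi_n, pi_s, len(codon_idx)
    )


def compare_gene_sets(genes: list[GeneDiversity]) -> dict:
    """Median π_N/π_S per gene set plus a Kruskal–Wallis test.

    Genes without a defined ratio (π_S = 0 or no usable codons) are
    excluded from the medians and reported per group.  H uses the tie
    correction and the χ² approximation with df = groups − 1.
    """
    groups: dict[str, list[float]] = {}
    excluded: dict[str, int] = {}
    for g in genes:
        r = g.ratio
        if np.isfinite(r):
            groups.setdefault(g.gene_set, []).append(r)
        else:
            excluded[g.gene_set] = excluded.get(g.gene_set, 0) + 1
            groups.setdefault(g.gene_set, [])
    empty = [k for k, v in groups.items() if len(v) < 2]
    if empty:
        raise ValueError(f"gene sets with <2 defined ratios: {empty}")
    if len(groups) < 2:
        raise ValueError("need at least 2 gene sets")
    labels = sorted(groups)
    samples = [groups[k] for k in labels]
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        H, P = 0.0, 1.0
    else:
        H, P = stats.kruskal(*samples)
    return {
        "medians": {k: float(np.median(groups[k])) for k in labels},
        "n_genes": {k: len(groups[k]) for k in labels},
        "n_excluded": {k: excluded.get(k, 0) for k in labels},
        "kruskal_H": float(H),
        "df": len(labels) - 1,
        "p_value": float(P),
    }


# ---------------------------------------------------------------------------
# McDonald–Kreitman


def mkt_alpha(Pn: float, Ps: float, Dn: float, Ds: float) -> MKTResult:
    """Classic MKT: α = 1 − (Ds·Pn)/(Dn·Ps), Fisher exact P on the 2×2 table."""
    if min(Pn, Ps, Dn, Ds) < 0:
        raise ValueError("MKT counts must be non-negative")
    res = MKTResult(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds)
    if Ps == 0 or Dn == 0:
        res.alpha_undefined = True
    else:
        res.alpha = 1.0 - (Ds * Pn) / (Dn * Ps)
    table = np.array([[Pn, Ps], [Dn, Ds]])
    if table.sum() > 0:
        res.p_value = float(stats.fisher_exact(np.round(table).astype(int))[1])
    return res


def asymptotic_alpha(bin_x: np.ndarray, bin_alpha: np.ndarray) -> MKTResult:
    """Asymptotic MKT: fit α(x) = a + b·exp(−c·x), report α(1).

    Requires ≥ 4 frequency bins with defined α.  The exponential fit
    uses fixed starting values (a = last bin's α, b = −0.5, c = 1) and
    c bounded to [0, 50]; on failure a linear extrapolation to x = 1 is
    used and flagged.
    """
    bin_x = np.asarray(bin_x, dtype=float)
    bin_alpha = np.asarray(bin_alpha, dtype=float)
    ok = np.isfinite(bin_alpha)
    if ok.sum() < 4:
        raise ValueError("need at least 4 frequency bins with defined alpha")
    x, y = bin_x[ok], bin_alpha[ok]
    res = MKTResult(Pn=np.nan, Ps=np.nan, Dn=np.nan, Ds=np.nan)
    res.bin_x, res.bin_alpha = x, y

    def model(x, a, b, c):
        return a + b * np.exp(-c * x)

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(y[-1], -0.5, 1.0),
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 50.0]),
            maxfev=10000,
        )
        res.fit_a, res.fit_b, res.fit_c = map(float, popt)
        res.alpha_asymptotic = float(model(1.0, *popt))
    except RuntimeError:
        slope, intercept = np.polyfit(x, y, 1)
        res.alpha_asymptotic = float(slope + intercept)
        res.linear_fallback = True
        logger.warning("asymptotic MKT fit failed; linear extrapolation used")
    res.alpha = res.alpha_asymptotic
    return res


def mkt_counts(
    alignment: CodonAlignment, n_bins: int | None = None
) -> tuple[float, float, float, float, pd.DataFrame]:
    """Polymorphism/divergence counts (Pn, Ps, Dn, Ds) for one gene.

    Ingroup codon columns with exactly two variants contribute
    polymorphisms (derived frequency polarized by the outgroup when it
    matches one variant); columns fixed in the ingroup but differing
    from the outgroup contribute divergence.  Columns with more than
    two ingroup variants or ambiguity are skipped.  Returns the four
    counts plus a per-frequency-bin table for the asymptotic MKT.
    """
    if alignment.outgroup is None:
        raise ValueError("MKT requires an outgroup sequence")
    ids = alignment.ingroup_ids()
    out = alignment.sequences[alignment.outgroup].upper()
    mask = alignment.column_mask
    n = len(ids)
    bins = n_bins or max(n - 1, 1)
    Pn = Ps = Dn = Ds = 0.0
    poly = []  # (freq, nd, sd)
    for k in range(alignment.length // 3):
        if mask[3 * k : 3 * k + 3].any():
            continue
        cods = [alignment.sequences[i][3 * k : 3 * k + 3].upper() for i in ids]
        oc = out[3 * k : 3 * k + 3]
        if not all(_codon_ok(c) for c in cods):
            continue
        variants = sorted(set(cods))
        if len(variants) == 1:
            if _codon_ok(oc) and oc != variants[0]:
                nd, sd = codon_path_diffs(variants[0], oc)
                Dn += nd
                Ds += sd
        elif len(variants) == 2:
            nd, sd = codon_path_diffs(variants[0], variants[1])
            Pn += nd
            Ps += sd
            if _codon_ok(oc) and oc in variants:
                derived = variants[1] if oc == variants[0] else variants[0]
            else:
                derived = min(variants, key=cods.count)  # minor as fallback
            freq = cods.count(derived) / n
            poly.append((freq, nd, sd))
    freq_table = pd.DataFrame(poly, columns=["freq", "nd", "sd"])
    edges = np.linspace(0, 1, bins + 1)
    rows = []
    for i in range(bins):
        lo, hi = edges[i], edges[i + 1]
        sel = (freq_table["freq"] > lo) & (freq_table["freq"] <= hi)
        rows.append(
            (
                (lo + hi) / 2,
                float(freq_table.loc[sel, "nd"].sum()),
                float(freq_table.loc[sel, "sd"].sum()),
            )
        )
    binned = pd.DataFrame(rows, columns=["x", "Pn", "Ps"])
    return Pn, Ps, Dn, Ds, binned


# ---------------------------------------------------------------------------
# building codon alignments from a site matrix


def build_codon_alignments(
    sites: SiteMatrix,
    reference: dict[str, str],
    genes: list[GeneModel],
    samples: list[str] | None = None,
    outgroup: dict[str, str] | None = None,
    exclude_regions: list[tuple[str, int, int]] | None = None,
    mask_threshold: float = 0.005,
    mask_window: int = 100,
    mask_step: int = 50,
    mask_mode: str = "window",
) -> list[CodonAlignment]:
    """Per-gene codon alignments from per-sample alternative references.

    Each sample's genome is the reference with its SNP calls applied;
    missing calls become ``N`` in the extracted CDS.  When an outgroup
    genome is supplied, its CDS is added and the divergence mask
    (reference vs outgroup) is applied to all sequences.  Genes
    overlapping ``exclude_regions`` (e.g. the HGT mask BED, where
    host-read mis-mapping corrupts the calls) are dropped entirely.
    """
    ids = samples if samples is not None else list(sites.samples)
    genomes: dict[str, dict[str, str]] = {}
    for s in ids:
        seqs, masks = apply_variants_to_reference(reference, s, sites)
        for chrom, ivs in masks.items():
            if ivs:
                arr = np.frombuffer(seqs[chrom].encode(), dtype="S1").copy()
                for a, b in ivs:
                    arr[a:b] = b"N"
                seqs[chrom] = arr.tobytes().decode()
        genomes[s] = seqs

    alignments = []
    for gene in genes:
        if exclude_regions and any(
            gene.chrom == c and gene.span[0] < e and gene.span[1] > s_
            for c, s_, e in exclude_regions
        ):
            logger.info("gene %s overlaps a masked region; excluded", gene.gene_id)
            continue
        seqs = {s: extract_cds(genomes[s], gene) for s in ids}
        col_mask = None
        out_id = None
        if outgroup is not None:
            out_id = "outgroup"
            out_cds = extract_cds(outgroup, gene)
            ref_cds = extract_cds(reference, gene)
            if mask_mode == "window":
                col_mask = mask_divergent_regions(
                    ref_cds, out_cds, mask_threshold, mask_window, mask_step
                )
            elif mask_mode == "gene":
                # whole-gene exclusion alternative: drop genes whose overall
                # divergence to the outgroup exceeds the threshold
                full = mask_divergent_regions(
                    ref_cds, out_cds, mask_threshold, window=len(ref_cds)
                )
                if full.any():
                    logger.info("gene %s exceeds divergence threshold; excluded", gene.gene_id)
                    continue
            else:
                raise ValueError("mask_mode must be 'window' or 'gene'")
            seqs[out_id] = out_cds
        alignments.append(
            CodonAlignment(
                gene.gene_id, seqs, column_mask=col_mask,
                gene_set=gene.gene_set, outgroup=out_id,
            )
        )
    return alignments
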