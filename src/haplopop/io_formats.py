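"""Standard-format I/O and the all-sites site matrix.

Everything downstream operates on a :class:`SiteMatrix`: per-site
haploid allele calls (plus per-genotype read depth) for every sample
over *all* genomic positions, invariant sites included.  Keeping
invariant and missing calls explicit is what makes the windowed
diversity estimator's denominators honest.

Coordinate conventions: internal coordinates are 0-based half-open
everywhere; VCF and GFF3 keep their native 1-based conventions at the
file boundary, BED is 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

__all__ = [
    "SiteMatrix",
    "GeneModel",
    "MISSING",
    "ALLELES",
    "read_all_sites_vcf",
    "write_all_sites_vcf",
    "apply_variants_to_reference",
    "extract_cds",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_metadata",
    "write_metadata",
    "read_gene_sets",
]

ALLELES = "ACGT"
#: allele code for a missing (or filtered-out) call
MISSING = 4

_CODE = {b: i for i, b in enumerate(ALLELES)}

# site classes
INVARIANT, SNP, EXCLUDED = 0, 1, 2


@dataclass
class SiteMatrix:
    """Haploid allele calls and depths for all samples at all retained sites.

    Attributes
    ----------
    chrom_names, chrom_lengths
        Chromosome ids and their lengths (bp).
    chrom_index, pos
        Per-site chromosome index (into ``chrom_names``) and 0-based
        position, genome-ordered.
    samples
        Sample ids, column order of ``alleles`` and ``depth``.
    ref
        Reference allele code per site.
    alleles
        ``(n_sites, n_samples)`` int8 codes (0..3 = ACGT, 4 = missing).
    depth
        ``(n_sites, n_samples)`` read depth; 0 where unknown.
    """

    chrom_names: list[str]
    chrom_lengths: list[int]
    chrom_index: np.ndarray
    pos: np.ndarray
    samples: list[str]
    ref: np.ndarray
    alleles: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int8)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.alleles.shape != (len(self.pos), len(self.samples)):
            raise ValueError("allele matrix shape does not match sites x samples")
        if self.depth.shape != self.alleles.shape:
            raise ValueError("depth matrix shape does not match allele matrix")
        for c in range(len(self.chrom_names)):
            p = self.pos[self.chrom_index == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on {self.chrom_names[c]}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def site_classes(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Per-site class: 0 invariant, 1 SNP, 2 excluded (no calls)."""
        a = self.alleles if columns is None else self.alleles[:, columns]
        counts = _allele_counts(a)
        n_distinct = (counts > 0).sum(axis=1)
        cls = np.full(self.n_sites, EXCLUDED, dtype=np.int8)
        cls[n_distinct == 1] = INVARIANT
        cls[n_distinct >= 2] = SNP
        return cls

    def n_alleles(self) -> np.ndarray:
        """Number of distinct non-missing alleles per site."""
        return (_allele_counts(self.alleles) > 0).sum(axis=1)

    def subset_samples(self, ids: list[str]) -> "SiteMatrix":
        idx = self.sample_index(ids)
        return replace(
            self,
            samples=list(ids),
            alleles=self.alleles[:, idx].copy(),
            depth=self.depth[:, idx].copy(),
        )

    def chrom_sites(self, chrom: str) -> np.ndarray:
        c = self.chrom_names.index(chrom)
        return np.flatnonzero(self.chrom_index == c)


def _allele_counts(alleles: np.ndarray) -> np.ndarray:
    """(n_sites, 4) counts of each base among non-missing calls."""
    counts = np.empty((alleles.shape[0], 4), dtype=np.int32)
    for b in range(4):
        counts[:, b] = (alleles == b).sum(axis=1)
    return counts


@dataclass(frozen=True)
class GeneModel:
    """Spliced CDS coordinates of one gene.

    ``cds_intervals`` are 0-based half-open, stored in transcription
    order (for minus-strand genes that is decreasing genomic order).
    ``gene_set`` partitions genes into a focal conserved set (BUSCO-like)
    versus the genomic background.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    gene_set: str = "background"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s0, e0), (s1, e1) in itertools.pairwise(ivs):
            if e0 > s1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.gene_id} ({self.cds_length}) not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.cds_intervals), max(e for _, e in self.cds_intervals)


# ---------------------------------------------------------------------------
# all-sites VCF


def read_all_sites_vcf(path: str, sample_subset: list[str] | None = None) -> SiteMatrix:
    """Read an all-sites VCF with haploid GT and per-genotype DP.

    Indel records are dropped; multiallelic SNPs are retained; ``.``
    genotypes map to missing.  Diploid-style genotypes (``0/1``) and
    unsorted input are errors.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in samples]
        if unknown:
            raise KeyError(f"samples not in VCF: {unknown}")
        keep = [samples.index(s) for s in sample_subset]
        out_samples = list(sample_subset)
    else:
        keep = list(range(len(samples)))
        out_samples = samples

    chrom_names = list(vcf.seqnames)
    lens = {c: int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)}
    chrom_lengths = [lens[c] for c in chrom_names]
    chrom_of = {c: i for i, c in enumerate(chrom_names)}

    ci, pos, ref, allele_rows, depth_rows = [], [], [], [], []
    last: tuple[int, int] | None = None
    for rec in vcf:
        alts = [a for a in rec.ALT if a != "<NON_REF>"]
        if rec.is_indel or len(rec.REF) != 1 or any(len(a) != 1 or a == "*" for a in alts):
            continue
        c = chrom_of[rec.CHROM]
        key = (c, rec.POS)
        if last is not None and key <= last:
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        last = key
        allele_codes = [_CODE[rec.REF.upper()]] + [_CODE[a.upper()] for a in alts]
        row = np.full(len(keep), MISSING, dtype=np.int8)
        for j, si in enumerate(keep):
            gt = rec.genotypes[si]
            if len(gt) != 2:  # [a0, a1, ..., phased] with >1 allele slot
                raise ValueError(
                    f"non-haploid genotype for sample {samples[si]} at {rec.CHROM}:{rec.POS}"
                )
            if gt[0] >= 0:
                row[j] = allele_codes[gt[0]]
        dp = rec.format("DP")
        if dp is None:
            drow = np.zeros(len(keep), dtype=np.int32)
        else:
            drow = dp.reshape(-1)[keep].astype(np.int64)
            drow = np.where(drow < 0, 0, drow).astype(np.int32)
        ci.append(c)
        pos.append(rec.POS - 1)  # VCF is 1-based
        ref.append(allele_codes[0])
        allele_rows.append(row)
        depth_rows.append(drow)

    n = len(pos)
    return SiteMatrix(
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        chrom_index=np.array(ci, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        samples=out_samples,
        ref=np.array(ref, dtype=np.int8),
        alleles=np.vstack(allele_rows) if n else np.empty((0, len(keep)), dtype=np.int8),
        depth=np.vstack(depth_rows) if n else np.empty((0, len(keep)), dtype=np.int32),
    )


def write_all_sites_vcf(sites: SiteMatrix, path: str) -> None:
    """Write a SiteMatrix back to an all-sites VCF v4.2 (GT and DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in zip(sites.chrom_names, sites.chrom_lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sites.samples)
            + "\n"
        )
        for i in range(sites.n_sites):
            r = int(sites.ref[i])
            row = sites.alleles[i]
            alts = sorted({int(a) for a in row if a != MISSING and a != r})
            codes = [r] + alts
            idx = {a: j for j, a in enumerate(codes)}
            alt_field = ",".join(ALLELES[a] for a in alts) if alts else "."
            gts = [
                f"{idx[int(a)]}:{int(d)}" if a != MISSING else f".:{int(d)}"
                for a, d in zip(row, sites.depth[i])
            ]
            fh.write(
                f"{sites.chrom_names[sites.chrom_index[i]]}\t{sites.pos[i] + 1}\t.\t"
                f"{ALLELES[r]}\t{alt_field}\t.\tPASS\t.\tGT:DP\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# per-sample genomes and CDS extraction


def apply_variants_to_reference(
    reference: dict[str, str], sample: str, sites: SiteMatrix
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Build a sample's alternative reference genome.

    Returns the per-chromosome sequences (identical to the reference
    except at the sample's non-reference calls) and a per-chromosome
    mask track of 0-based half-open intervals where the sample's call
    is missing (the emitted base there is the reference base and should
    not be trusted).
    """
    for c, length in zip(sites.chrom_names, sites.chrom_lengths):
        if c not in reference:
            raise ValueError(f"reference missing chromosome {c}")
        if len(reference[c]) != length:
            raise ValueError(
                f"reference length mismatch on {c}: "
                f"{len(reference[c])} vs declared {length}"
            )
    j = sites.sample_index([sample])[0]
    seqs: dict[str, str] = {}
    masks: dict[str, list[tuple[int, int]]] = {}
    for c, name in enumerate(sites.chrom_names):
        idx = np.flatnonzero(sites.chrom_index == c)
        seq = np.frombuffer(reference[name].upper().encode(), dtype="S1").copy()
        if len(idx) and sites.pos[idx].max() >= len(seq):
            raise ValueError(f"site position beyond end of {name}")
        calls = sites.alleles[idx, j]
        called = calls != MISSING
        subst = idx[called]
        seq[sites.pos[subst]] = np.frombuffer(
            ALLELES.encode(), dtype="S1"
        )[sites.alleles[subst, j]]
        seqs[name] = seq.tobytes().decode()
        masks[name] = _as_intervals(np.sort(sites.pos[idx[~called]]))
    return seqs, masks


def _as_intervals(positions: np.ndarray) -> list[tuple[int, int]]:
    """Collapse sorted positions into half-open intervals."""
    out: list[tuple[int, int]] = []
    for p in positions:
        p = int(p)
        if out and out[-1][1] == p:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def extract_cds(genome: dict[str, str], gene: GeneModel) -> str:
    """Concatenate a gene's CDS intervals in transcription order.

    Minus-strand genes are reverse-complemented.  The result's length
    must be divisible by 3 (enforced by :class:`GeneModel`); an
    interval outside the chromosome is an error, never trimmed.
    """
    chrom = genome[gene.chrom]
    for s, e in gene.cds_intervals:
        if s < 0 or e > len(chrom) or s >= e:
            raise ValueError(
                f"CDS interval [{s}, {e}) of {gene.gene_id} outside {gene.chrom}"
            )
    parts = [chrom[s:e] for s, e in sorted(gene.cds_intervals)]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED / TSV


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path,
        "fasta",
    )


def read_gff3(path: str, gene_sets: dict[str, str] | None = None) -> list[GeneModel]:
    """Read CDS features grouped by gene id from a GFF3 file.

    The GFF3 phase column is ignored; total CDS length divisibility by
    3 is enforced instead.  ``gene_sets`` optionally maps gene ids to a
    set label (defaults to ``background``).
    """
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    by_gene: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", cds.attributes.get("ID", ["?"]))[0]
        by_gene.setdefault(parent, []).append(cds)
    for gid, feats in sorted(by_gene.items()):
        chrom = feats[0].seqid
        strand = feats[0].strand
        ivs = tuple(sorted((f.start - 1, f.end) for f in feats))  # GFF3 is 1-based inclusive
        label = (gene_sets or {}).get(gid, "background")
        genes.append(GeneModel(gid, chrom, strand, ivs, gene_set=label))
    return genes


def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s0, e0 = g.span
            fh.write(
                f"{g.chrom}\thaplopop\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e in sorted(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\thaplopop\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_bed(regions: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_metadata(path: str) -> pd.DataFrame:
    """Sample metadata TSV: sample, lat, lon, mean_depth, lineage."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "lineage": str})
    required = {"sample", "lat", "lon", "mean_depth", "lineage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if (meta["lat"].abs() > 90).any() or (meta["lon"].abs() > 180).any():
        raise ValueError("coordinates out of range")
    if (meta["mean_depth"] <= 0).any():
        raise ValueError("mean depth must be > 0")
    return meta.set_index("sample", drop=False)


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str) -> dict[str, str]:
    """Two-column TSV (gene id, set label) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "set"], dtype=str)
    return dict(zip(df["gene"], df["set"]))
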