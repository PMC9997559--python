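"""Synthetic datasets with the structure of a Holarctic haploid parasite.

The generator emulates the sampling design the analysis assumes: a
small (scaled-down) multi-chromosome haploid genome, ten samples in
three geographic lineages (5/2/3) whose splits are deep relative to
within-lineage diversity, protein-coding genes under strong versus
relaxed purifying constraint, a handful of windows whose apparent
diversity is artifactually inflated by host-to-parasite HGT
mis-mapping, per-genotype read depths, sequencing-read evidence for
ploidy inference, and sampling coordinates that produce isolation by
distance.

The model is deliberately minimal: a forced-join genealogy (Kingman
coalescent within each lineage, lineage roots joined exactly at the
split times T2 and T1), infinite-sites single-nucleotide mutations
dropped as a Poisson process at the clock rate per site per *year*
(conversion to generations is the clock module's business), and
purifying selection reduced to an acceptance probability for
nonsynonymous candidate changes (classified against the reference
codon).  No recombination, migration, or indels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ALLELES, MISSING, GeneModel, SiteMatrix
from .selection import _CODON_AA

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TreeNode",
    "SyntheticDataset",
    "simulate_genealogy",
    "drop_mutations",
    "emit_read_evidence",
    "inject_hgt_contamination",
    "generate_dataset",
    "write_dataset",
]

_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G on allele codes

# sampling sites and mean coverages of the ten-sample 5/2/3 design
_DEFAULT_SAMPLE_TABLE = {
    "WEurasia": [
        (59.8312191, 23.2577045, 19.0),
        (59.8329692, 23.2562571, 26.0),
        (52.4535830, -1.9194440, 71.0),
        (67.68696, 12.67197, 70.0),
        (55.303833, 63.405333, 21.0),
    ],
    "EAsia": [
        (46.825017, 124.378953, 10.0),
        (53.017833, 106.886833, 29.0),
    ],
    "NAmerica": [
        (44.3332, -68.0632, 40.0),
        (44.3331, -68.0629, 55.0),
        (44.3336, -68.0636, 37.0),
    ],
}

_LINEAGE_CENTERS = {
    "WEurasia": (59.0, 23.0),
    "EAsia": (50.0, 116.0),
    "NAmerica": (44.3, -68.1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions: a 12 x 20 kb genome
    (the full genome, ~2.3 Mb in 12 chromosomes, is reached by raising
    ``chrom_length``), three lineages sampled 5/2/3, split times
    T1 = 1.61 Myr (Western Eurasia vs the rest) and T2 = 0.5 Myr
    (East Asia vs North America), within-lineage diversity theta per
    site far below the between-lineage divergence 2 r T, and a clock
    rate r per site per year matching the calibrated estimate.
    """

    n_chromosomes: int = 12
    chrom_length: int = 20_000
    lineages: tuple[str, ...] = ("WEurasia", "EAsia", "NAmerica")
    samples_per_lineage: tuple[int, ...] = (5, 2, 3)
    split_t1: float = 1.61e6  # years, WEurasia vs (EAsia + NAmerica)
    split_t2: float = 0.5e6  # years, EAsia vs NAmerica
    theta: float = 1e-4  # within-lineage pairwise diversity per site
    clock_rate: float = 1.04e-9  # substitutions / site / year
    n_genes: int = 120
    gene_codons: int = 333
    focal_fraction: float = 0.5  # fraction of genes in the conserved set
    f_constrained: float = 0.1  # nonsynonymous acceptance, focal set
    f_relaxed: float = 0.5  # nonsynonymous acceptance, background
    hgt_windows: tuple[tuple[str, int, int], ...] = (
        ("chr2", 10_000, 11_000),
        ("chr5", 10_000, 11_000),
        ("chr8", 10_000, 11_000),
    )
    hgt_divergence: float = 0.05
    hgt_sample_fraction: float = 0.5
    mean_depth: float | None = None  # None: per-sample defaults of the 5/2/3 design
    seq_error: float = 0.01
    ploidy: dict[str, int] = field(default_factory=dict)  # default haploid
    outgroup_divergence: float = 0.003
    coord_scatter_deg: float = 2.0
    kmer_k: int = 21
    kmer_het_fraction: float = 0.4
    kmer_n_species: int = 50_000

    def __post_init__(self) -> None:
        if not self.split_t1 > self.split_t2 > 0:
            raise ValueError("need T1 > T2 > 0")
        for f in (self.f_constrained, self.f_relaxed, self.focal_fraction):
            if not 0 <= f <= 1:
                raise ValueError("acceptance probabilities must be in [0, 1]")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("sequencing error must be in [0, 0.5)")
        if min(self.samples_per_lineage) < 1:
            raise ValueError("need at least 1 sample per lineage")
        if len(self.samples_per_lineage) != len(self.lineages):
            raise ValueError("samples_per_lineage must match lineages")

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for name, n in zip(self.lineages, self.samples_per_lineage):
            out += [f"{name}_{i + 1}" for i in range(n)]
        return out

    @property
    def lineage_of(self) -> dict[str, str]:
        return {
            s: name
            for name, n in zip(self.lineages, self.samples_per_lineage)
            for s in (f"{name}_{i + 1}" for i in range(n))
        }

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length

    @property
    def ne_years(self) -> float:
        """Within-lineage effective size expressed in years (theta = 2 Ne r)."""
        if self.clock_rate <= 0:
            return 0.0
        return self.theta / (2.0 * self.clock_rate)


@dataclass
class TreeNode:
    """Node of the sample genealogy; times in years before present."""

    time: float
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    leaves: frozenset[int] = frozenset()  # sample column indices below

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def branches(self) -> list[tuple["TreeNode", float]]:
        """(child node, branch length in years) for every non-root node."""
        out = []
        for node in self.postorder():
            for c in node.children:
                out.append((c, node.time - c.time))
        return out


def _index_leaves(root: TreeNode) -> None:
    for node in root.postorder():
        if not node.children:
            node.leaves = frozenset(node.leaves)
        else:
            node.leaves = frozenset().union(*(c.leaves for c in node.children))


def simulate_genealogy(config: SimulationConfig, seed: int) -> TreeNode:
    """Forced-join genealogy over the sampled haploid genomes.

    Within each lineage a Kingman coalescent with effective size
    theta / (2 r) (in years) runs to its MRCA, conditioned to finish
    before the lineage joins its sister; the East Asian and North
    American roots join at exactly T2 and that ancestor joins the
    Western Eurasian root at exactly T1.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    ids = config.sample_ids
    col = {s: i for i, s in enumerate(ids)}
    roots: dict[str, TreeNode] = {}
    join_time = {
        config.lineages[0]: config.split_t1,
        config.lineages[1]: config.split_t2,
        config.lineages[2]: config.split_t2,
    }
    for name, n in zip(config.lineages, config.samples_per_lineage):
        tips = [
            TreeNode(0.0, name=f"{name}_{i + 1}", leaves=frozenset([col[f"{name}_{i + 1}"]]))
            for i in range(n)
        ]
        roots[name] = _kingman(tips, config.ne_years, join_time[name], rng)
    inner = TreeNode(config.split_t2, children=[roots[config.lineages[1]], roots[config.lineages[2]]])
    root = TreeNode(config.split_t1, children=[roots[config.lineages[0]], inner])
    _index_leaves(root)
    return root


def _kingman(tips: list[TreeNode], ne: float, t_max: float, rng) -> TreeNode:
    if len(tips) == 1:
        return tips[0]
    if ne <= 0:  # degenerate: star coalescence at time 0
        node = TreeNode(0.0, children=list(tips))
        return node
    for _ in range(1000):
        nodes = list(tips)
        t = 0.0
        ok = True
        merges: list[tuple[int, int, float]] = []
        k = len(nodes)
        order = list(range(k))
        while k > 1:
            rate = k * (k - 1) / 2 / ne
            t += rng.exponential(1.0 / rate)
            if t >= t_max:
                ok = False
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            merges.append((i, j, t))
            k -= 1
        if ok:
            for i, j, t in merges:
                parent = TreeNode(t, children=[nodes[i], nodes[j]])
                nodes[i] = parent
                nodes.pop(j)
            return nodes[0]
    raise RuntimeError("within-lineage coalescence did not finish before the split")


# ---------------------------------------------------------------------------
# reference genome and gene models


def generate_reference(config: SimulationConfig, seed: int) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference genome with stop-free single-exon CDS gene models.

    Genes are spread evenly over chromosomes, alternate strand and
    gene-set label (focal conserved set vs background), and their
    reading frames contain no stop codons so every reference codon has
    defined NG86 site counts.
    """
    rng = np.random.default_rng(seed)
    non_stop = [c for c in _CODON_AA if _CODON_AA[c] != "*"]
    genes: list[GeneModel] = []
    reference: dict[str, str] = {}
    gene_len = 3 * config.gene_codons
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    g = 0
    n_focal_target = int(round(config.focal_fraction * config.n_genes))
    for chrom in config.chrom_names:
        seq = rng.integers(0, 4, size=config.chrom_length)
        ref = "".join(ALLELES[b] for b in seq)
        arr = list(ref)
        slots = max(per_chrom, 1)
        spacing = config.chrom_length // slots
        if spacing < gene_len + 100:
            raise ValueError("chromosome too short for the requested gene layout")
        for k in range(slots):
            if g >= config.n_genes:
                break
            start = k * spacing + (spacing - gene_len) // 2
            cds = "".join(rng.choice(non_stop) for _ in range(config.gene_codons))
            strand = "+" if g % 2 == 0 else "-"
            if strand == "-":
                ins = str(_revcomp(cds))
            else:
                ins = cds
            arr[start : start + gene_len] = list(ins)
            # alternate labels so both sets are spread over the genome
            label = "focal_set" if (g % 2 == 0 and g < 2 * n_focal_target) else "background"
            genes.append(
                GeneModel(f"g{g + 1:04d}", chrom, strand, ((start, start + gene_len),), gene_set=label)
            )
            g += 1
        reference[chrom] = "".join(arr)
    return reference, genes


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class _CodingIndex:
    """Maps genome positions to (gene, CDS offset) for mutation classification."""

    def __init__(self, config: SimulationConfig, reference: dict[str, str], genes: list[GeneModel]):
        self.gene_no = {c: np.full(config.chrom_length, -1, dtype=np.int32) for c in config.chrom_names}
        self.offset = {c: np.zeros(config.chrom_length, dtype=np.int32) for c in config.chrom_names}
        self.genes = genes
        self.cds: list[str] = []
        for gi, gene in enumerate(genes):
            positions: list[int] = []
            for s, e in sorted(gene.cds_intervals):
                positions.extend(range(s, e))
            if gene.strand == "-":
                positions = positions[::-1]
            for off, p in enumerate(positions):
                self.gene_no[gene.chrom][p] = gi
                self.offset[gene.chrom][p] = off
            raw = "".join(reference[gene.chrom][s:e] for s, e in sorted(gene.cds_intervals))
            self.cds.append(_revcomp(raw) if gene.strand == "-" else raw)

    def classify(self, chrom: str, pos: int, derived_code: int) -> tuple[str | None, bool]:
        """(gene set of the hit gene or None, is_nonsynonymous)."""
        gi = int(self.gene_no[chrom][pos])
        if gi < 0:
            return None, False
        gene = self.genes[gi]
        off = int(self.offset[chrom][pos])
        code = derived_code if gene.strand == "+" else _COMP[derived_code]
        cds = self.cds[gi]
        c0 = 3 * (off // 3)
        codon = cds[c0 : c0 + 3]
        within = off % 3
        new = codon[:within] + ALLELES[code] + codon[within + 1 :]
        return gene.gene_set, _CODON_AA[new] != _CODON_AA[codon]


def drop_mutations(
    tree: TreeNode,
    reference: dict[str, str],
    genes: list[GeneModel],
    config: SimulationConfig,
    seed: int,
) -> tuple[SiteMatrix, pd.DataFrame]:
    """Poisson mutations on the genealogy, thinned by purifying selection.

    Mutations arise at ``clock_rate`` per site per year on every
    branch; each is a single-nucleotide change at a previously unhit
    site (infinite sites within a run).  In coding regions a
    nonsynonymous candidate (classified against the reference codon)
    is accepted with probability f_constrained (focal set) or
    f_relaxed (background); synonymous and intergenic changes are
    always accepted.  Returns the all-sites matrix (ancestral state =
    reference) plus a truth table of accepted mutations.
    """
    rng = np.random.default_rng(seed)
    ids = config.sample_ids
    n = len(ids)
    L = config.genome_length
    chrom_len = config.chrom_length
    branches = tree.branches()
    lengths = np.array([b[1] for b in branches], dtype=float)
    total = lengths.sum()
    ref_codes = np.concatenate(
        [
            np.frombuffer(reference[c].encode(), dtype=np.uint8)
            for c in config.chrom_names
        ]
    )
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(ALLELES):
        lut[ord(b)] = i
    ref_codes = lut[ref_codes]
    alleles = np.repeat(ref_codes[:, None], n, axis=1).astype(np.int8)

    coding = _CodingIndex(config, reference, genes)
    accept = {"focal_set": config.f_constrained, "background": config.f_relaxed}
    n_mut = rng.poisson(config.clock_rate * total * L) if total > 0 else 0
    used: set[int] = set()
    records = []
    if n_mut:
        probs = lengths / total
        branch_idx = rng.choice(len(branches), size=n_mut, p=probs)
        for bi in branch_idx:
            site = int(rng.integers(0, L))
            if site in used:
                continue  # infinite sites: recurrent hits rejected
            chrom = config.chrom_names[site // chrom_len]
            pos = site % chrom_len
            anc = int(ref_codes[site])
            derived = int((anc + 1 + rng.integers(0, 3)) % 4)
            gene_set, nonsyn = coding.classify(chrom, pos, derived)
            if gene_set is not None and nonsyn and rng.random() >= accept[gene_set]:
                continue
            used.add(site)
            carriers = sorted(branches[bi][0].leaves)
            alleles[site, carriers] = derived
            records.append(
                (chrom, pos, ALLELES[anc], ALLELES[derived], gene_set or "intergenic", nonsyn, len(carriers))
            )
    truth = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ancestral", "derived", "gene_set", "nonsynonymous", "n_carriers"],
    )
    sites = SiteMatrix(
        chrom_names=config.chrom_names,
        chrom_lengths=[chrom_len] * config.n_chromosomes,
        chrom_index=np.repeat(np.arange(config.n_chromosomes, dtype=np.int32), chrom_len),
        pos=np.tile(np.arange(chrom_len, dtype=np.int64), config.n_chromosomes),
        samples=ids,
        ref=ref_codes,
        alleles=alleles,
        depth=np.zeros((L, n), dtype=np.int32),
    )
    return sites, truth


# ---------------------------------------------------------------------------
# read-level evidence


@dataclass
class ReadEvidence:
    depth: np.ndarray  # (n_sites, n_samples)
    support: pd.DataFrame  # sample, chrom, pos, depth, alt_count at biallelic SNPs
    kmer_histograms: dict[str, Counter]


def emit_read_evidence(sites: SiteMatrix, config: SimulationConfig, seed: int) -> ReadEvidence:
    """Per-site depths, allele-support counts, and k-mer spectra.

    Depth is Poisson around the sample's mean coverage.  At biallelic
    SNP sites, a haploid sample's alternate-read support is
    Binomial(depth, sequencing error); a diploid sample's heterozygous
    sites (where its two haplotypes differ) get Binomial(depth, 0.5).
    The k-mer spectrum is emulated parametrically as a Poisson mixture:
    one mode at the coverage for haploids, modes at half and full
    coverage for diploids.
    """
    rng = np.random.default_rng(seed)
    ids = list(sites.samples)
    depths = _mean_depths(config, ids)
    n_sites = sites.n_sites
    depth = np.column_stack([rng.poisson(depths[s], size=n_sites) for s in ids]).astype(np.int32)

    biallelic = np.flatnonzero(sites.n_alleles() == 2)
    partner = _diploid_partners(config, ids)
    rows = []
    for j, s in enumerate(ids):
        d = depth[biallelic, j]
        het = np.zeros(len(biallelic), dtype=bool)
        if config.ploidy.get(s, 1) == 2:
            pj = ids.index(partner[s])
            a, b = sites.alleles[biallelic, j], sites.alleles[biallelic, pj]
            het = (a != b) & (a != MISSING) & (b != MISSING)
        p = np.where(het, 0.5, config.seq_error)
        alt = rng.binomial(d, p)
        chroms = [sites.chrom_names[c] for c in sites.chrom_index[biallelic]]
        rows.append(
            pd.DataFrame(
                {
                    "sample": s,
                    "chrom": chroms,
                    "pos": sites.pos[biallelic],
                    "depth": d,
                    "alt_count": alt,
                }
            )
        )
    support = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample", "chrom", "pos", "depth", "alt_count"]
    )

    kmer_hists: dict[str, Counter] = {}
    n_species = min(config.kmer_n_species, max(sites.n_sites - config.kmer_k + 1, 1))
    for s in ids:
        c = depths[s]
        if config.ploidy.get(s, 1) == 2:
            n_half = int(round(config.kmer_het_fraction * n_species))
            mult = np.concatenate(
                [rng.poisson(c / 2.0, size=n_half), rng.poisson(c, size=n_species - n_half)]
            )
        else:
            mult = rng.poisson(c, size=n_species)
        mult = mult[mult > 0]
        kmer_hists[s] = Counter(mult.tolist())
    return ReadEvidence(depth, support, kmer_hists)


def _mean_depths(config: SimulationConfig, ids: list[str]) -> dict[str, float]:
    if config.mean_depth is not None:
        return {s: float(config.mean_depth) for s in ids}
    if tuple(config.samples_per_lineage) == (5, 2, 3) and tuple(config.lineages) == (
        "WEurasia",
        "EAsia",
        "NAmerica",
    ):
        out = {}
        for name in config.lineages:
            for i, (_, _, cov) in enumerate(_DEFAULT_SAMPLE_TABLE[name]):
                out[f"{name}_{i + 1}"] = cov
        return out
    return {s: 30.0 for s in ids}


def _diploid_partners(config: SimulationConfig, ids: list[str]) -> dict[str, str]:
    """Second haplotype donor for diploid controls.

    The donor comes from across the deepest split (the first lineage
    vs the rest) so a diploid control carries heterozygosity at the
    full between-lineage divergence.
    """
    lineage = config.lineage_of
    deep = config.lineages[0]
    partner = {}
    for s in ids:
        if config.ploidy.get(s, 1) == 2:
            if lineage[s] == deep:
                others = [o for o in ids if lineage[o] != deep]
            else:
                others = [o for o in ids if lineage[o] == deep]
            partner[s] = others[ids.index(s) % len(others)] if others else s
    return partner


def inject_hgt_contamination(
    sites: SiteMatrix,
    windows: list[tuple[str, int, int]],
    divergence: float,
    seed: int,
    sample_fraction: float = 0.5,
    genes: list[GeneModel] | None = None,
) -> SiteMatrix:
    """Inflate apparent diversity inside HGT windows.

    Emulates host reads mis-mapping onto horizontally transferred
    segments: inside each window a random subset of samples receives
    "host" alleles at the given per-site divergence.  Outside the
    windows the matrix is unchanged; divergence 0 or an empty window
    list is the identity.
    """
    out = replace(sites, alleles=sites.alleles.copy(), depth=sites.depth.copy())
    if not windows or divergence == 0:
        return out
    rng = np.random.default_rng(seed)
    n = sites.n_samples
    for chrom, start, end in windows:
        c = sites.chrom_names.index(chrom)
        idx = np.flatnonzero(
            (sites.chrom_index == c) & (sites.pos >= start) & (sites.pos < end)
        )
        contaminated = np.flatnonzero(rng.random(n) < sample_fraction)
        if len(contaminated) == 0:
            contaminated = np.array([int(rng.integers(0, n))])
        hit = rng.random((len(idx), len(contaminated))) < divergence
        shift = rng.integers(1, 4, size=hit.sum())
        rows, cols = np.nonzero(hit)
        cur = out.alleles[idx[rows], contaminated[cols]]
        host = np.where(cur == MISSING, rng.integers(0, 4, size=len(cur)), (cur + shift) % 4)
        out.alleles[idx[rows], contaminated[cols]] = host.astype(np.int8)
        if genes:
            overlapping = [
                g.gene_id
                for g in genes
                if g.chrom == chrom and g.span[0] < end and g.span[1] > start
            ]
            if overlapping:
                logger.info(
                    "HGT window %s:%d-%d overlaps genes %s", chrom, start, end, overlapping
                )
    return out


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: TreeNode
    reference: dict[str, str]
    outgroup: dict[str, str]
    genes: list[GeneModel]
    sites: SiteMatrix
    truth: pd.DataFrame
    metadata: pd.DataFrame
    evidence: ReadEvidence
    hgt_windows: list[tuple[str, int, int]]


def generate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Run the full generator: genealogy, mutations, evidence, HGT, metadata."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_ref, s_mut, s_ev, s_hgt, s_out, s_coord = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7)
    ]
    tree = simulate_genealogy(config, s_tree)
    reference, genes = generate_reference(config, s_ref)
    sites, truth = drop_mutations(tree, reference, genes, config, s_mut)
    sites = inject_hgt_contamination(
        sites,
        list(config.hgt_windows),
        config.hgt_divergence,
        s_hgt,
        config.hgt_sample_fraction,
        genes,
    )
    evidence = emit_read_evidence(sites, config, s_ev)
    sites.depth = evidence.depth
    outgroup = _make_outgroup(reference, genes, config, s_out)
    metadata = _make_metadata(config, s_coord)
    return SyntheticDataset(
        config, tree, reference, outgroup, genes, sites, truth, metadata, evidence,
        list(config.hgt_windows),
    )


def _make_outgroup(
    reference: dict[str, str], genes: list[GeneModel], config: SimulationConfig, seed: int
) -> dict[str, str]:
    """Outgroup genome at a given candidate per-site divergence, selection-thinned."""
    rng = np.random.default_rng(seed)
    coding = _CodingIndex(config, reference, genes)
    accept = {"focal_set": config.f_constrained, "background": config.f_relaxed}
    out = {}
    for chrom in config.chrom_names:
        arr = list(reference[chrom])
        hits = np.flatnonzero(rng.random(len(arr)) < config.outgroup_divergence)
        for pos in hits:
            anc = arr[pos]
            derived_code = (ALLELES.index(anc) + 1 + int(rng.integers(0, 3))) % 4
            gene_set, nonsyn = coding.classify(chrom, int(pos), derived_code)
            if gene_set is not None and nonsyn and rng.random() >= accept[gene_set]:
                continue
            arr[pos] = ALLELES[derived_code]
        out[chrom] = "".join(arr)
    return out


def _make_metadata(config: SimulationConfig, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    depths = _mean_depths(config, config.sample_ids)
    rows = []
    default_design = tuple(config.samples_per_lineage) == (5, 2, 3) and tuple(
        config.lineages
    ) == ("WEurasia", "EAsia", "NAmerica")
    for name, n in zip(config.lineages, config.samples_per_lineage):
        for i in range(n):
            s = f"{name}_{i + 1}"
            if default_design:
                lat, lon, _ = _DEFAULT_SAMPLE_TABLE[name][i]
            else:
                clat, clon = _LINEAGE_CENTERS.get(name, (50.0, 0.0))
                lat = float(np.clip(clat + rng.normal(0, config.coord_scatter_deg), -89, 89))
                lon = float(clon + rng.normal(0, config.coord_scatter_deg))
            rows.append((s, lat, lon, depths[s], name))
    return pd.DataFrame(
        rows, columns=["sample", "lat", "lon", "mean_depth", "lineage"]
    ).set_index("sample", drop=False)


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the dataset in standard formats; returns the path map."""
    import os

    from .io_formats import (
        write_all_sites_vcf,
        write_bed,
        write_fasta,
        write_gff3,
        write_metadata,
    )

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "all_sites.vcf"),
        "reference": os.path.join(outdir, "reference.fasta"),
        "outgroup": os.path.join(outdir, "outgroup.fasta"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "hgt_bed": os.path.join(outdir, "hgt_windows.bed"),
        "metadata": os.path.join(outdir, "samples.tsv"),
        "gene_sets": os.path.join(outdir, "gene_sets.tsv"),
        "support": os.path.join(outdir, "allele_support.tsv"),
        "kmer": os.path.join(outdir, "kmer_histograms.tsv"),
    }
    write_all_sites_vcf(ds.sites, paths["vcf"])
    write_fasta(ds.reference, paths["reference"])
    write_fasta(ds.outgroup, paths["outgroup"])
    write_gff3(ds.genes, paths["gff3"])
    write_bed(ds.hgt_windows, paths["hgt_bed"])
    write_metadata(ds.metadata, paths["metadata"])
    with open(paths["gene_sets"], "w") as fh:
        for g in ds.genes:
            fh.write(f"{g.gene_id}\t{g.gene_set}\n")
    ds.evidence.support.to_csv(paths["support"], sep="\t", index=False)
    with open(paths["kmer"], "w") as fh:
        fh.write("sample\tmultiplicity\tcount\n")
        for s, hist in ds.evidence.kmer_histograms.items():
            for mult in sorted(hist):
                fh.write(f"{s}\t{mult}\t{hist[mult]}\n")
    return paths
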