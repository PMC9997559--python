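"""End-to-end orchestration: io -> ploidy -> diversity -> selection -> structure -> clock.

A single :class:`PipelineConfig` (YAML-friendly) names either a
simulate block or input paths, plus per-stage parameters and a global
seed.  ``run_pipeline`` executes the enabled stages in dependency
order, writes each stage's TSV/JSON into the output directory, and
returns a machine-readable summary.  Identical config + seed gives
byte-identical numeric output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import clock as clock_mod
from . import diversity as div_mod
from . import io_formats as io_mod
from . import ploidy as ploidy_mod
from . import selection as sel_mod
from . import structure as struct_mod
from .synthetic import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

ALL_STAGES = ("ploidy", "diversity", "selection", "structure", "clock")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict[str, Any] | None = None  # SimulationConfig overrides
    inputs: dict[str, str] = field(default_factory=dict)  # vcf/reference/outgroup/gff3/hgt_bed/metadata/gene_sets/support/kmer
    stages: tuple[str, ...] = ALL_STAGES
    window_size: int = 1000
    percentiles: tuple[float, float] = (95.0, 99.0)
    depth_low: float = 0.5
    depth_high: float = 2.0
    kmer_k: int = 21
    min_informative_sites: int = 100
    n_permutations: int = 1000
    split_time_years: float = 1.61e6
    generation_time_h: float = 63.0
    resting_months: tuple[float, ...] = (0.0, 4.0, 6.0)
    rate_per_year: float | None = None  # externally calibrated clock rate
    rate_bounds: tuple[float, float] | None = None
    divergence_mask_mode: str = "window"  # or "gene": whole-gene exclusion

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "percentiles", "resting_months", "rate_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DataBundle:
    sites: io_mod.SiteMatrix
    reference: dict[str, str]
    genes: list[io_mod.GeneModel]
    metadata: pd.DataFrame
    hgt_regions: list[tuple[str, int, int]]
    outgroup: dict[str, str] | None = None
    support: pd.DataFrame | None = None
    kmer_histograms: dict[str, Counter] | None = None


def load_inputs(cfg: PipelineConfig) -> DataBundle:
    """Materialise the data bundle from a simulate block or input files."""
    if cfg.simulate is not None:
        sim = SimulationConfig(**cfg.simulate)
        ds = generate_dataset(sim, cfg.seed)
        write_dataset(ds, os.path.join(cfg.outdir, "data"))
        return DataBundle(
            ds.sites, ds.reference, ds.genes, ds.metadata, ds.hgt_windows,
            outgroup=ds.outgroup, support=ds.evidence.support,
            kmer_histograms=ds.evidence.kmer_histograms,
        )
    required = ("vcf", "reference", "gff3", "metadata")
    missing = [k for k in required if k not in cfg.inputs]
    if missing:
        raise ValueError(f"missing inputs: {missing}")
    gene_sets = (
        io_mod.read_gene_sets(cfg.inputs["gene_sets"]) if "gene_sets" in cfg.inputs else None
    )
    bundle = DataBundle(
        sites=io_mod.read_all_sites_vcf(cfg.inputs["vcf"]),
        reference=io_mod.read_fasta(cfg.inputs["reference"]),
        genes=io_mod.read_gff3(cfg.inputs["gff3"], gene_sets),
        metadata=io_mod.read_metadata(cfg.inputs["metadata"]),
        hgt_regions=io_mod.read_bed(cfg.inputs["hgt_bed"]) if "hgt_bed" in cfg.inputs else [],
    )
    if "outgroup" in cfg.inputs:
        bundle.outgroup = io_mod.read_fasta(cfg.inputs["outgroup"])
    if "support" in cfg.inputs:
        bundle.support = pd.read_csv(cfg.inputs["support"], sep="\t")
    if "kmer" in cfg.inputs:
        km = pd.read_csv(cfg.inputs["kmer"], sep="\t")
        bundle.kmer_histograms = {
            s: Counter(dict(zip(g["multiplicity"], g["count"])))
            for s, g in km.groupby("sample")
        }
    return bundle


# ---------------------------------------------------------------------------
# stages


def stage_ploidy(bundle: DataBundle, cfg: PipelineConfig) -> pd.DataFrame:
    if bundle.support is None:
        raise ValueError("ploidy stage needs an allele-support table")
    rows = []
    for s in bundle.sites.samples:
        hist = ploidy_mod.allele_balance_histogram(bundle.support, s)
        peaks = None
        if bundle.kmer_histograms and s in bundle.kmer_histograms:
            peaks = ploidy_mod.detect_spectrum_peaks(bundle.kmer_histograms[s])
        call = ploidy_mod.call_ploidy(
            hist, peaks, sample=s, min_informative=cfg.min_informative_sites
        )
        rows.append(
            (s, call.verdict, call.band_mass, call.n_informative, ",".join(map(str, call.peaks)))
        )
    table = pd.DataFrame(
        rows, columns=["sample", "verdict", "het_band_mass", "n_informative", "spectrum_peaks"]
    )
    table.to_csv(os.path.join(cfg.outdir, "ploidy.tsv"), sep="\t", index=False)
    return table


def stage_diversity(bundle: DataBundle, cfg: PipelineConfig) -> dict[str, Any]:
    filtered = div_mod.depth_filter(
        bundle.sites, bundle.metadata, cfg.depth_low, cfg.depth_high
    )
    out: dict[str, Any] = {}
    table_all = div_mod.windowed_pi(filtered, window=cfg.window_size, lineage="all")
    tables = [table_all]
    for lineage, grp in bundle.metadata.groupby("lineage"):
        ids = list(grp["sample"])
        if len(ids) < 2:
            continue
        t = div_mod.windowed_pi(filtered, ids, window=cfg.window_size, lineage=lineage)
        tables.append(t)
    flagged = []
    for t in tables:
        try:
            flagged.append(
                div_mod.flag_outlier_windows(t, cfg.percentiles, bundle.hgt_regions)
            )
        except ValueError:
            flagged.append(t)
    full = pd.concat(flagged, ignore_index=True)
    full.to_csv(os.path.join(cfg.outdir, "diversity_windows.tsv"), sep="\t", index=False)
    classes = filtered.site_classes()
    out["snp_count"] = int((classes == 1).sum())
    defined = table_all["pi"].dropna()
    out["genome_pi"] = float(defined.mean()) if len(defined) else float("nan")
    out["per_lineage_pi"] = {
        t["lineage"].iloc[0]: float(t["pi"].dropna().mean()) for t in tables[1:]
    }
    out["_filtered_sites"] = filtered
    return out


def stage_selection(bundle: DataBundle, cfg: PipelineConfig) -> dict[str, Any]:
    alignments = sel_mod.build_codon_alignments(
        bundle.sites, bundle.reference, bundle.genes, outgroup=bundle.outgroup,
        exclude_regions=bundle.hgt_regions, mask_mode=cfg.divergence_mask_mode,
    )
    diversities = [sel_mod.gene_pi_n_s(a) for a in alignments]
    per_gene = pd.DataFrame(
        [
            (d.gene_id, d.gene_set, d.n_sites, d.s_sites, d.pi_n, d.pi_s, d.ratio)
            for d in diversities
        ],
        columns=["gene", "set", "N_sites", "S_sites", "piN", "piS", "ratio"],
    )
    per_gene.to_csv(os.path.join(cfg.outdir, "gene_diversity.tsv"), sep="\t", index=False)
    comparison = sel_mod.compare_gene_sets(diversities)
    out: dict[str, Any] = {"gene_set_comparison": comparison}
    if bundle.outgroup is not None:
        Pn = Ps = Dn = Ds = 0.0
        binned_sum: pd.DataFrame | None = None
        for a in alignments:
            pn, ps, dn, dsv, binned = sel_mod.mkt_counts(a)
            Pn, Ps, Dn, Ds = Pn + pn, Ps + ps, Dn + dn, Ds + dsv
            binned_sum = binned if binned_sum is None else binned_sum.assign(
                Pn=binned_sum["Pn"] + binned["Pn"], Ps=binned_sum["Ps"] + binned["Ps"]
            )
        mkt = sel_mod.mkt_alpha(Pn, Ps, Dn, Ds)
        out["mkt"] = {
            "Pn": Pn, "Ps": Ps, "Dn": Dn, "Ds": Ds,
            "alpha": None if mkt.alpha_undefined else mkt.alpha,
            "fisher_p": mkt.p_value,
        }
        if binned_sum is not None and Dn > 0 and Ds > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha_x = 1.0 - (Ds / Dn) * (
                    binned_sum["Pn"].to_numpy() / binned_sum["Ps"].to_numpy()
                )
            defined = np.isfinite(alpha_x)
            if defined.sum() >= 4:
                asym = sel_mod.asymptotic_alpha(binned_sum["x"].to_numpy(), alpha_x)
                out["mkt"]["alpha_asymptotic"] = asym.alpha_asymptotic
    with open(os.path.join(cfg.outdir, "selection.json"), "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    out["_alignments"] = alignments
    return out


def stage_structure(bundle: DataBundle, cfg: PipelineConfig) -> dict[str, Any]:
    geno = struct_mod.genotype_matrix(bundle.sites)
    scores, var_frac = struct_mod.pca_genotypes(geno)
    k = bundle.metadata["lineage"].nunique()
    labels = struct_mod.cluster_samples(scores, max(k, 2), var_frac, seed=cfg.seed)
    relatedness = struct_mod.allele_sharing_relatedness(geno)
    meta = bundle.metadata.loc[bundle.sites.samples]
    distances = struct_mod.geodesic_matrix(meta)
    dbmem = struct_mod.build_dbmem(distances)
    ibd = struct_mod.rda_ibd_test(
        relatedness, dbmem, n_perm=cfg.n_permutations, seed=cfg.seed
    )
    pd.DataFrame(
        scores, index=bundle.sites.samples,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    ).to_csv(os.path.join(cfg.outdir, "pca_scores.tsv"), sep="\t")
    pd.DataFrame({"variance_fraction": var_frac}).to_csv(
        os.path.join(cfg.outdir, "pca_variance.tsv"), sep="\t", index=False
    )
    relatedness.to_csv(os.path.join(cfg.outdir, "relatedness.tsv"), sep="\t")
    distances.to_csv(os.path.join(cfg.outdir, "distances_km.tsv"), sep="\t")
    result = {
        "n_snps": geno.n_snps,
        "variance_fractions": [float(v) for v in var_frac[: min(5, len(var_frac))]],
        "cluster_labels": dict(zip(bundle.sites.samples, map(int, labels))),
        "ibd": dataclasses.asdict(ibd),
    }
    with open(os.path.join(cfg.outdir, "ibd.json"), "w") as fh:
        json.dump(result["ibd"], fh, indent=2)
    return result


def stage_clock(
    bundle: DataBundle | None,
    cfg: PipelineConfig,
    alignments: list[sel_mod.CodonAlignment] | None = None,
) -> dict[str, Any]:
    """Clock rate (external or distance-calibrated) and mu conversions."""
    out: dict[str, Any] = {
        "split_time_years": cfg.split_time_years,
        "generation_time_h": cfg.generation_time_h,
    }
    if cfg.rate_per_year is not None:
        rate, bounds = cfg.rate_per_year, cfg.rate_bounds
        out["rate_source"] = "external"
    else:
        if alignments is None:
            if bundle is None:
                raise ValueError("clock stage needs alignments or an external rate")
            alignments = sel_mod.build_codon_alignments(
                bundle.sites, bundle.reference, bundle.genes, outgroup=bundle.outgroup,
                exclude_regions=bundle.hgt_regions,
            )
        concat = concatenated_fourfold(alignments)
        dist = clock_mod.pairwise_distance(concat)
        focal = set(
            bundle.metadata.loc[bundle.metadata["lineage"] == "WEurasia", "sample"]
        )
        between = dist[
            dist.apply(lambda r: (r["sample_a"] in focal) != (r["sample_b"] in focal), axis=1)
        ]
        d = float(between["jc69"].mean())
        rate = clock_mod.strict_clock_rate(d, cfg.split_time_years)
        bounds = None
        out["rate_source"] = "fourfold_strict_clock"
        out["mean_between_clade_jc69"] = d
        out["n_fourfold_sites"] = int(between["n_sites"].iloc[0]) if len(between) else 0
    out["rate_per_year"] = rate
    if bounds is not None:
        out["rate_bounds"] = list(bounds)
    out["mu_per_generation"] = {}
    for months in cfg.resting_months:
        params = clock_mod.LifeCycleParams(cfg.generation_time_h, months)
        est = clock_mod.ClockEstimate(rate, bounds, cfg.split_time_years, params)
        entry = {
            "mu": est.mu_per_generation,
            "mu_3sf": float(f"{est.mu_per_generation:.3g}"),
            "generations_per_year": clock_mod.generations_per_year(params),
        }
        if est.mu_bounds is not None:
            entry["mu_bounds"] = list(est.mu_bounds)
            entry["mu_bounds_3sf"] = [float(f"{b:.3g}") for b in est.mu_bounds]
        out["mu_per_generation"][f"resting_{months:g}_months"] = entry
    with open(os.path.join(cfg.outdir, "clock.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def concatenated_fourfold(alignments: list[sel_mod.CodonAlignment]) -> dict[str, str]:
    """Concatenate 4-fold degenerate columns across genes, ingroup samples only."""
    parts: dict[str, list[str]] = {}
    for a in alignments:
        ingroup = a.ingroup_ids()
        sub = sel_mod.CodonAlignment(
            a.gene_id,
            {i: a.sequences[i] for i in ingroup},
            column_mask=a.column_mask,
            gene_set=a.gene_set,
        )
        cols = clock_mod.fourfold_degenerate_columns(sub)
        for i in ingroup:
            s = a.sequences[i]
            parts.setdefault(i, []).append("".join(s[c] for c in cols))
    return {i: "".join(p) for i, p in parts.items()}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    os.makedirs(cfg.outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline seed=%d outdir=%s stages=%s", cfg.seed, cfg.outdir, cfg.stages)
    summary: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "seed": cfg.seed}
    bundle = load_inputs(cfg) if (cfg.simulate is not None or cfg.inputs) else None
    if bundle is None and set(cfg.stages) - {"clock"}:
        raise ValueError("all stages except clock-with-external-rate need input data")
    alignments = None
    if bundle is not None and "ploidy" in cfg.stages:
        table = stage_ploidy(bundle, cfg)
        summary["ploidy"] = dict(zip(table["sample"], table["verdict"]))
    if bundle is not None and "diversity" in cfg.stages:
        res = stage_diversity(bundle, cfg)
        bundle.sites = res.pop("_filtered_sites")  # downstream stages use filtered calls
        summary["diversity"] = res
    if bundle is not None and "selection" in cfg.stages:
        res = stage_selection(bundle, cfg)
        alignments = res.pop("_alignments")
        summary["selection"] = res
    if bundle is not None and "structure" in cfg.stages:
        summary["structure"] = stage_structure(bundle, cfg)
    if "clock" in cfg.stages:
        summary["clock"] = stage_clock(bundle, cfg, alignments)
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
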