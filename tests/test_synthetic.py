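import dataclasses

import numpy as np
import pytest

from haplopop.io_formats import MISSING
from haplopop.structure import vincenty_km
from haplopop.synthetic import (
    SimulationConfig,
    drop_mutations,
    emit_read_evidence,
    generate_dataset,
    generate_reference,
    inject_hgt_contamination,
    simulate_genealogy,
)


def mrca_time(tree, names):
    """Time of the most recent node covering all the named samples."""
    want = set(names)
    best = None
    for node in tree.postorder():
        leaves = {n.name for n in node.postorder() if not n.children}
        if want <= leaves and (best is None or node.time < best):
            best = node.time
    return best


class TestGenealogy:
    def test_one_sample_per_lineage_forces_split_nodes(self):
        cfg = SimulationConfig(samples_per_lineage=(1, 1, 1))
        tree = simulate_genealogy(cfg, seed=0)
        internal = sorted(n.time for n in tree.postorder() if n.children)
        assert internal == [cfg.split_t2, cfg.split_t1]

    def test_same_seed_identical_tree(self, default_config):
        t1 = simulate_genealogy(default_config, seed=5)
        t2 = simulate_genealogy(default_config, seed=5)
        assert [(n.time, n.name) for n in t1.postorder()] == [
            (n.time, n.name) for n in t2.postorder()
        ]

    def test_pairwise_coalescent_time_matches_kingman_expectation(self):
        """Mean within-lineage pair coalescent time is Ne (in years)."""
        cfg = SimulationConfig(samples_per_lineage=(2, 1, 1))
        times = [
            mrca_time(simulate_genealogy(cfg, seed=s), ["WEurasia_1", "WEurasia_2"])
            for s in range(1000)
        ]
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - cfg.ne_years) < 3 * se

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError, match="at least 1 sample"):
            SimulationConfig(samples_per_lineage=(5, 0, 3))


class TestDropMutations:
    def test_zero_rate_means_all_invariant(self):
        cfg = SimulationConfig(clock_rate=0.0)
        tree = simulate_genealogy(cfg, seed=1)
        ref, genes = generate_reference(cfg, seed=1)
        sites, truth = drop_mutations(tree, ref, genes, cfg, seed=1)
        assert len(truth) == 0
        assert (sites.site_classes() == 0).all()

    def test_full_constraint_blocks_nonsynonymous_in_focal_genes(self):
        cfg = SimulationConfig(f_constrained=0.0)
        tree = simulate_genealogy(cfg, seed=2)
        ref, genes = generate_reference(cfg, seed=2)
        _, truth = drop_mutations(tree, ref, genes, cfg, seed=2)
        focal = truth[truth["gene_set"] == "focal_set"]
        assert len(focal) > 0
        assert not focal["nonsynonymous"].any()

    def test_between_lineage_divergence_matches_poisson_expectation(self):
        """Intergenic WEurasia-vs-rest divergence ~ 2 r T1."""
        cfg = SimulationConfig()
        diffs = comps = 0
        for seed in range(1, 6):
            tree = simulate_genealogy(cfg, seed=seed)
            ref, genes = generate_reference(cfg, seed=seed)
            sites, _ = drop_mutations(tree, ref, genes, cfg, seed=seed)
            coding = np.zeros(sites.n_sites, dtype=bool)
            for g in genes:
                c = sites.chrom_names.index(g.chrom)
                s0, e0 = g.span
                coding |= (sites.chrom_index == c) & (sites.pos >= s0) & (sites.pos < e0)
            a = sites.alleles[~coding]
            we = [i for i, s in enumerate(sites.samples) if s.startswith("WEurasia")]
            rest = [i for i in range(sites.n_samples) if i not in we]
            for i in we:
                for j in rest:
                    diffs += int((a[:, i] != a[:, j]).sum())
                    comps += a.shape[0]
        p = diffs / comps
        expected = 2 * cfg.clock_rate * cfg.split_t1
        se = np.sqrt(expected / comps * 25 * 5)  # pairs share branches; generous SE
        assert abs(p - expected) < max(3 * se, 0.15 * expected)


class TestReadEvidence:
    def test_zero_error_haploid_has_no_alternate_support(self):
        cfg = SimulationConfig(seq_error=0.0)
        ds = generate_dataset(cfg, 3)
        assert (ds.evidence.support["alt_count"] == 0).all()

    def test_bad_error_rate_rejected(self):
        with pytest.raises(ValueError, match="sequencing error"):
            SimulationConfig(seq_error=0.6)

    def test_diploid_heterozygous_support_is_balanced(self):
        """Minor-read fraction at heterozygous sites centers on 0.5."""
        ids = SimulationConfig().sample_ids
        cfg = SimulationConfig(mean_depth=40.0, ploidy={ids[0]: 2})
        ds = generate_dataset(cfg, 4)
        sup = ds.evidence.support
        rows = sup[(sup["sample"] == ids[0]) & (sup["alt_count"] >= 5)]
        frac = rows["alt_count"] / rows["depth"]
        het = frac[(frac > 0.2) & (frac < 0.8)]
        assert len(het) > 200
        assert abs(het.mean() - 0.5) < 0.02

    def test_determinism(self, default_config):
        e1 = emit_read_evidence(generate_dataset(default_config, 5).sites, default_config, 9)
        e2 = emit_read_evidence(generate_dataset(default_config, 5).sites, default_config, 9)
        assert e1.support.equals(e2.support)
        assert e1.kmer_histograms == e2.kmer_histograms
        np.testing.assert_array_equal(e1.depth, e2.depth)


class TestHgtInjection:
    def test_zero_divergence_is_identity(self, dataset):
        out = inject_hgt_contamination(dataset.sites, [("chr1", 0, 1000)], 0.0, seed=1)
        np.testing.assert_array_equal(out.alleles, dataset.sites.alleles)

    def test_empty_window_list_is_identity(self, dataset):
        out = inject_hgt_contamination(dataset.sites, [], 0.1, seed=1)
        np.testing.assert_array_equal(out.alleles, dataset.sites.alleles)

    def test_outside_windows_unchanged(self, default_config):
        cfg = dataclasses.replace(default_config, hgt_windows=())
        ds = generate_dataset(cfg, 6)
        out = inject_hgt_contamination(ds.sites, [("chr3", 5000, 6000)], 0.2, seed=2)
        c = ds.sites.chrom_names.index("chr3")
        inside = (ds.sites.chrom_index == c) & (ds.sites.pos >= 5000) & (ds.sites.pos < 6000)
        np.testing.assert_array_equal(
            out.alleles[~inside], ds.sites.alleles[~inside]
        )
        assert (out.alleles[inside] != ds.sites.alleles[inside]).any()


class TestDatasetProperties:
    def test_full_determinism(self, default_config):
        d1 = generate_dataset(default_config, 11)
        d2 = generate_dataset(default_config, 11)
        np.testing.assert_array_equal(d1.sites.alleles, d2.sites.alleles)
        np.testing.assert_array_equal(d1.sites.depth, d2.sites.depth)
        assert d1.reference == d2.reference
        assert d1.outgroup == d2.outgroup
        assert d1.metadata.equals(d2.metadata)

    def test_within_diversity_far_below_between_divergence(self, dataset):
        a = dataset.sites.alleles
        ids = dataset.sites.samples
        we = [i for i, s in enumerate(ids) if s.startswith("WEurasia")]
        na = [i for i, s in enumerate(ids) if s.startswith("NAmerica")]
        within = np.mean([(a[:, we[0]] != a[:, j]).mean() for j in we[1:]])
        between = np.mean([(a[:, we[0]] != a[:, j]).mean() for j in na])
        assert within * 5 < between

    def test_geography_mirrors_lineages(self, dataset):
        meta = dataset.metadata
        within, between = [], []
        rows = list(meta.itertuples())
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                d = vincenty_km(a.lat, a.lon, b.lat, b.lon)
                (within if a.lineage == b.lineage else between).append(d)
        # continental scatter overlaps a little (e.g. Britain-Urals), but on
        # average lineages are geographically compact relative to their spread
        assert np.mean(within) < 0.5 * np.mean(between)
        assert np.median(within) < min(between)
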