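import itertools

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from haplopop.selection import (
    CodonAlignment,
    asymptotic_alpha,
    codon_path_diffs,
    compare_gene_sets,
    gene_pi_n_s,
    mask_divergent_regions,
    mkt_alpha,
    ng86_site_counts,
)

AA = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    AA[stop] = "*"


def oracle_path_diffs(c1, c2):
    """Independent pathway enumeration (stops excluded, averaged)."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(pos):
        cur, nd, sd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if AA[nxt] == "*":
                ok = False
                break
            nd += AA[cur] != AA[nxt]
            sd += AA[cur] == AA[nxt]
            cur = nxt
        if ok:
            results.append((nd, sd))
    if not results:
        return float(len(pos)), 0.0
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNg86SiteCounts:
    def test_methionine_is_fully_nonsynonymous(self):
        assert ng86_site_counts("ATG") == (3.0, 0.0)

    def test_fourfold_third_position(self):
        n, s = ng86_site_counts("GGG")
        assert (n, s) == (2.0, 1.0)

    def test_leucine_third_position_is_one_third_synonymous(self):
        # TTA: TTG synonymous at position 3; CTA synonymous at position 1
        n, s = ng86_site_counts("TTA")
        assert s == pytest.approx(2 / 3)
        assert n + s == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")

    def test_sites_sum_to_three_per_codon(self):
        total_n = total_s = 0.0
        codons = [c for c in AA if AA[c] != "*"]
        for c in codons:
            n, s = ng86_site_counts(c)
            total_n += n
            total_s += s
        assert total_n + total_s == pytest.approx(3.0 * len(codons))


class TestCodonPathDiffs:
    def test_identical_codons(self):
        assert codon_path_diffs("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        assert codon_path_diffs("GGA", "GGG") == (0.0, 1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        codons = [c for c in AA if AA[c] != "*"]
        for _ in range(200):
            c1, c2 = rng.choice(codons, size=2)
            assert codon_path_diffs(c1, c2) == pytest.approx(oracle_path_diffs(c1, c2))


class TestMaskDivergentRegions:
    def test_identical_sequences_unmasked(self):
        assert not mask_divergent_regions("ACGT" * 50, "ACGT" * 50).any()

    def test_one_difference_per_hundred_masks(self):
        a = "A" * 100
        b = "C" + "A" * 99
        assert mask_divergent_regions(a, b).all()

    def test_exactly_at_threshold_not_masked(self):
        # 1 difference in 200 columns = 0.005 exactly; strict > rule
        a = "A" * 200
        b = "C" + "A" * 199
        assert not mask_divergent_regions(a, b, window=200).any()

    def test_window_longer_than_alignment(self):
        a, b = "AAAA", "CAAA"
        assert mask_divergent_regions(a, b, window=100).all()


def alignment_from(seqs, gene_set="background", outgroup=None, mask=None):
    return CodonAlignment("g", seqs, column_mask=mask, gene_set=gene_set, outgroup=outgroup)


class TestGenePiNS:
    def test_identical_sequences_have_zero_diversity(self):
        aln = alignment_from({"a": "ATGGGA", "b": "ATGGGA"})
        d = gene_pi_n_s(aln)
        assert d.pi_n == 0.0 and d.pi_s == 0.0

    def test_one_synonymous_difference_with_25_syn_sites(self):
        # 25 GGN codons contribute exactly one synonymous site each
        s1 = "GGA" * 25
        s2 = "GGG" + "GGA" * 24
        d = gene_pi_n_s(alignment_from({"a": s1, "b": s2}))
        assert d.s_sites == pytest.approx(25.0)
        assert d.pi_s == pytest.approx(1 / 25)
        assert d.pi_n == 0.0

    def test_fully_masked_gene_is_flagged_undefined(self):
        aln = alignment_from(
            {"a": "ATGGGA", "b": "ATGGGA"}, mask=np.ones(6, dtype=bool)
        )
        d = gene_pi_n_s(aln)
        assert d.n_codons_used == 0 and np.isnan(d.pi_n)

    def test_matches_exhaustive_oracle_on_random_alignments(self):
        rng = np.random.default_rng(2)
        codons = [c for c in AA if AA[c] != "*"]
        for _ in range(25):
            n_seq = int(rng.integers(2, 6))
            n_cod = int(rng.integers(1, 11))
            base = rng.choice(codons, size=n_cod)
            seqs = {}
            for i in range(n_seq):
                mut = base.copy()
                for k in range(n_cod):
                    if rng.random() < 0.3:
                        mut[k] = rng.choice(codons)
                seqs[f"s{i}"] = "".join(mut)
            d = gene_pi_n_s(alignment_from(seqs))
            # independent oracle: average pathway diffs over explicit pairs
            ids = list(seqs)
            nd = sd = 0.0
            for a, b in itertools.combinations(ids, 2):
                for k in range(n_cod):
                    ca, cb = seqs[a][3 * k : 3 * k + 3], seqs[b][3 * k : 3 * k + 3]
                    dn, ds = oracle_path_diffs(ca, cb)
                    nd += dn
                    sd += ds
            n_pairs = len(ids) * (len(ids) - 1) / 2
            n_sites = np.mean(
                [sum(ng86_site_counts(s[3 * k : 3 * k + 3])[0] for k in range(n_cod)) for s in seqs.values()]
            )
            s_sites = np.mean(
                [sum(ng86_site_counts(s[3 * k : 3 * k + 3])[1] for k in range(n_cod)) for s in seqs.values()]
            )
            assert d.pi_n == pytest.approx((nd / n_pairs) / n_sites)
            assert d.pi_s == pytest.approx((sd / n_pairs) / s_sites)


class TestCompareGeneSets:
    def test_identical_groups_give_null_statistic(self):
        from haplopop.selection import GeneDiversity

        genes = [
            GeneDiversity(f"g{i}", gs, 10.0, 5.0, 0.01, 0.1, 10)
            for i in range(4)
            for gs in ("focal_set", "background")
        ]
        res = compare_gene_sets(genes)
        assert res["kruskal_H"] == 0.0 and res["p_value"] == 1.0

    def test_undefined_group_is_an_error(self):
        from haplopop.selection import GeneDiversity

        genes = [
            GeneDiversity("g1", "a", 10.0, 5.0, 0.0, 0.0, 10),
            GeneDiversity("g2", "a", 10.0, 5.0, 0.0, 0.0, 10),
            GeneDiversity("g3", "b", 10.0, 5.0, 0.01, 0.1, 10),
            GeneDiversity("g4", "b", 10.0, 5.0, 0.01, 0.1, 10),
        ]
        with pytest.raises(ValueError, match="a"):
            compare_gene_sets(genes)

    def test_constraint_ordering_is_monotone_in_acceptance_probability(self):
        """Median ratio of the relaxed set rises with its acceptance f."""
        import dataclasses

        from haplopop.selection import build_codon_alignments
        from haplopop.synthetic import SimulationConfig, generate_dataset

        medians = []
        for f_relaxed in (0.1, 0.4, 0.9):
            cfg = dataclasses.replace(
                SimulationConfig(), f_constrained=0.05, f_relaxed=f_relaxed
            )
            ds = generate_dataset(cfg, 31)
            alns = build_codon_alignments(
                ds.sites, ds.reference, ds.genes, exclude_regions=ds.hgt_windows
            )
            divs = [gene_pi_n_s(a) for a in alns]
            res = compare_gene_sets(divs)
            medians.append(res["medians"]["background"])
            assert res["medians"]["focal_set"] <= res["medians"]["background"]
        assert medians == sorted(medians)


class TestMkt:
    def test_neutral_symmetry(self):
        assert mkt_alpha(5, 5, 5, 5).alpha == pytest.approx(0.0)

    def test_adaptive_excess(self):
        res = mkt_alpha(2, 10, 10, 10)
        assert res.alpha == pytest.approx(0.8)

    def test_undefined_when_no_synonymous_polymorphism(self):
        res = mkt_alpha(5, 0, 10, 10)
        assert res.alpha_undefined
        assert np.isfinite(res.p_value)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mkt_alpha(-1, 1, 1, 1)

    def test_alpha_unstable_with_few_polymorphic_sites(self):
        """Bootstrap over <=10 polymorphic sites scatters alpha widely —
        the pathology that blocks reliable MKT at low diversity."""
        rng = np.random.default_rng(3)
        sites = ["N"] * 4 + ["S"] * 6  # 10 polymorphic coding sites
        Dn, Ds = 40, 35
        alphas = []
        for _ in range(200):
            pick = rng.choice(sites, size=len(sites), replace=True)
            Pn, Ps = int((pick == "N").sum()), int((pick == "S").sum())
            res = mkt_alpha(Pn, Ps, Dn, Ds)
            if not res.alpha_undefined:
                alphas.append(res.alpha)
        assert max(alphas) - min(alphas) > 0.5


class TestAsymptoticAlpha:
    def test_constant_alpha_is_recovered(self):
        x = np.linspace(0.1, 1.0, 8)
        res = asymptotic_alpha(x, np.full(8, 0.3))
        assert res.alpha_asymptotic == pytest.approx(0.3, abs=1e-6)

    def test_exponential_recovery_with_noise(self):
        rng = np.random.default_rng(4)
        a, b, c = 0.4, -0.3, 2.0
        x = np.linspace(0.05, 1.0, 15)
        y = a + b * np.exp(-c * x) + rng.normal(0, 0.01, size=len(x))
        res = asymptotic_alpha(x, y)
        assert abs(res.alpha_asymptotic - (a + b * np.exp(-c))) < 0.05

    def test_three_bins_rejected(self):
        with pytest.raises(ValueError, match="4"):
            asymptotic_alpha(np.array([0.2, 0.5, 0.8]), np.array([0.1, 0.2, 0.3]))
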