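import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from haplopop.structure import (
    BERING_WAYPOINT,
    GenotypeMatrix,
    allele_sharing_relatedness,
    build_dbmem,
    cluster_samples,
    genotype_matrix,
    geodesic_matrix,
    pca_genotypes,
    rda_ibd_test,
    vincenty_km,
)

# oracle distances computed once with geosphere::distGeo (WGS84)
GEO_ORACLE_KM = [
    ((0.0, 0.0), (0.0, 1.0), 111.319491),
    ((59.8312191, 23.2577045), (52.4535830, -1.9194440), 1752.494439),
    ((46.825017, 124.378953), BERING_WAYPOINT, 4328.610077),
    (BERING_WAYPOINT, (44.3332, -68.0632), 6093.175151),
    ((67.68696, 12.67197), (55.303833, 63.405333), 2920.921262),
]


def geno_from(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n = matrix.shape[0]
    return GenotypeMatrix(
        samples or [f"s{i}" for i in range(n)],
        ["chr1"] * matrix.shape[1],
        np.arange(matrix.shape[1]),
        matrix,
    )


class TestGenotypeMatrix:
    def test_multiallelic_and_invariant_sites_excluded(self, dataset):
        g = genotype_matrix(dataset.sites)
        n_alleles = dataset.sites.n_alleles()
        assert g.n_snps == int((n_alleles == 2).sum())
        # every column carries both alleles
        for j in range(0, g.n_snps, max(g.n_snps // 50, 1)):
            col = g.matrix[:, j]
            assert {0, 1} <= set(col[col >= 0].tolist())


class TestPca:
    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        X[1] = X[0]
        scores, _ = pca_genotypes(geno_from(X))
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-10)

    def test_variance_fractions_properties(self, dataset):
        _, vf = pca_genotypes(genotype_matrix(dataset.sites))
        assert np.all(np.diff(vf) <= 1e-12)
        assert np.all((vf >= 0) & (vf <= 1)) and vf.sum() <= 1 + 1e-9

    def test_sample_order_invariance_up_to_sign(self, dataset):
        g = genotype_matrix(dataset.sites)
        s1, v1 = pca_genotypes(g)
        perm = np.arange(len(g.samples))[::-1]
        g2 = GenotypeMatrix(
            [g.samples[i] for i in perm], g.chroms, g.positions, g.matrix[perm]
        )
        s2, v2 = pca_genotypes(g2)
        np.testing.assert_allclose(v1, v2, atol=1e-9)
        for k in range(2):
            col = s2[np.argsort(perm), k]
            assert np.allclose(col, s1[:, k], atol=1e-8) or np.allclose(
                col, -s1[:, k], atol=1e-8
            )


class TestClustering:
    def test_recovers_lineages(self, dataset):
        g = genotype_matrix(dataset.sites)
        scores, vf = pca_genotypes(g)
        labels = cluster_samples(scores, 3, vf, seed=0)
        truth = [s.split("_")[0] for s in dataset.sites.samples]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, dataset):
        g = genotype_matrix(dataset.sites)
        scores, vf = pca_genotypes(g)
        labels = cluster_samples(scores, len(g.samples), vf, seed=0)
        assert len(set(labels)) == len(g.samples)

    def test_deterministic_under_seed(self, dataset):
        g = genotype_matrix(dataset.sites)
        scores, vf = pca_genotypes(g)
        l1 = cluster_samples(scores, 3, vf, seed=7)
        l2 = cluster_samples(scores, 3, vf, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_k_below_two_rejected(self, dataset):
        g = genotype_matrix(dataset.sites)
        scores, vf = pca_genotypes(g)
        with pytest.raises(ValueError):
            cluster_samples(scores, 1, vf)


class TestRelatedness:
    def test_hand_computed_three_samples(self):
        X = np.array(
            [[0, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0]], dtype=np.int8
        )
        beta = allele_sharing_relatedness(geno_from(X)).to_numpy()
        M = np.array([[1, 0.5, 0.0], [0.5, 1, 0.5], [0.0, 0.5, 1]])
        m_bar = (0.5 + 0.0 + 0.5) / 3
        expected = (M - m_bar) / (1 - m_bar)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(beta, expected)

    def test_identical_pair_scores_one(self):
        X = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1]], dtype=np.int8)
        beta = allele_sharing_relatedness(geno_from(X))
        assert beta.iloc[0, 1] == pytest.approx(1.0)

    def test_mean_offdiagonal_is_zero(self, dataset):
        beta = allele_sharing_relatedness(genotype_matrix(dataset.sites)).to_numpy()
        tri = beta[np.triu_indices(len(beta), k=1)]
        assert tri.mean() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_pair_is_an_error(self):
        X = np.array([[0, -1], [-1, 1], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no genotyped"):
            allele_sharing_relatedness(geno_from(X))


class TestGeodesic:
    def test_identical_points(self):
        assert vincenty_km(10.0, 20.0, 10.0, 20.0) == 0.0

    @pytest.mark.parametrize("a,b,km", GEO_ORACLE_KM)
    def test_against_geodesy_oracle(self, a, b, km):
        assert vincenty_km(a[0], a[1], b[0], b[1]) == pytest.approx(km, abs=0.01)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            vincenty_km(95.0, 0.0, 0.0, 0.0)

    def test_routed_pair_is_sum_of_legs(self, dataset):
        meta = dataset.metadata
        D = geodesic_matrix(meta)
        a = meta.iloc[0]  # WEurasia
        b = meta[meta["lineage"] == "NAmerica"].iloc[0]
        legs = vincenty_km(a["lat"], a["lon"], *BERING_WAYPOINT) + vincenty_km(
            *BERING_WAYPOINT, b["lat"], b["lon"]
        )
        assert D.loc[a["sample"], b["sample"]] == pytest.approx(legs)

    def test_unrouted_pair_is_direct(self, dataset):
        meta = dataset.metadata
        D = geodesic_matrix(meta)
        a, b = meta.iloc[0], meta.iloc[1]  # both WEurasia
        assert D.loc[a["sample"], b["sample"]] == pytest.approx(
            vincenty_km(a["lat"], a["lon"], b["lat"], b["lon"])
        )


class TestDbmem:
    def collinear(self, n=6, spacing=0.5):
        return pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n)],
                "lat": [0.0] * n,
                "lon": [i * spacing for i in range(n)],
                "mean_depth": 10.0,
                "lineage": "X",
            }
        ).set_index("sample", drop=False)

    def test_first_axis_is_broadest_scale_on_collinear_points(self):
        """On a transect MEM1 is the single-sign-change, end-to-end trend."""
        D = geodesic_matrix(self.collinear(), routing=[])
        mem = build_dbmem(D)
        u = mem[:, 0]
        assert int((np.sign(u[:-1]) != np.sign(u[1:])).sum()) == 1
        rho = spearmanr(u, np.arange(len(u))).statistic
        assert abs(rho) > 0.8

    def test_axes_orthogonal(self, dataset):
        mem = build_dbmem(geodesic_matrix(dataset.metadata), autocor="all")
        norm = mem / np.linalg.norm(mem, axis=0)
        off = norm.T @ norm - np.eye(mem.shape[1])
        assert np.abs(off).max() < 1e-8

    def test_coincident_points_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="coincident"):
            build_dbmem(D)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_dbmem(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestRdaIbd:
    def test_identity_response_gives_r2_one(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(8)],
                "lat": rng.uniform(0, 10, 8),
                "lon": rng.uniform(0, 10, 8),
                "mean_depth": 10.0,
                "lineage": "X",
            }
        ).set_index("sample", drop=False)
        mem = build_dbmem(geodesic_matrix(pts, routing=[]))
        # response built from the predictors themselves
        Y = mem @ mem.T
        res = rda_ibd_test(Y, mem, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_p_value_floor_and_determinism(self, dataset):
        g = genotype_matrix(dataset.sites)
        rel = allele_sharing_relatedness(g)
        mem = build_dbmem(geodesic_matrix(dataset.metadata))
        r1 = rda_ibd_test(rel, mem, n_perm=199, seed=3)
        r2 = rda_ibd_test(rel, mem, n_perm=199, seed=3)
        assert r1 == r2
        assert r1.p_value >= 1 / 200

    def test_saturated_design_rejected(self):
        rng = np.random.default_rng(1)
        rel = np.eye(5)
        mem = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="saturated"):
            rda_ibd_test(rel, mem, n_perm=99, seed=0)

    def test_relatedness_declines_with_distance(self, dataset):
        """The synthetic default design shows the IBD signal."""
        g = genotype_matrix(dataset.sites)
        rel = allele_sharing_relatedness(g).to_numpy()
        D = geodesic_matrix(dataset.metadata).to_numpy()
        iu = np.triu_indices(len(rel), k=1)
        rho = spearmanr(rel[iu], D[iu]).statistic
        assert rho < -0.5


class TestStructureDepth:
    def test_recovery_degrades_with_shallow_splits(self):
        """Cluster recovery falls toward chance as splits approach zero."""
        from haplopop.synthetic import SimulationConfig, generate_dataset

        aris = []
        for t1, t2 in ((1.61e6, 5e5), (8e4, 2.5e4), (8e3, 2.5e3)):
            cfg = dataclasses.replace(SimulationConfig(), split_t1=t1, split_t2=t2)
            ds = generate_dataset(cfg, 13)
            g = genotype_matrix(ds.sites)
            scores, vf = pca_genotypes(g)
            labels = cluster_samples(scores, 3, vf, seed=0)
            truth = [s.split("_")[0] for s in ds.sites.samples]
            aris.append(adjusted_rand_score(truth, labels))
        assert aris[0] == 1.0
        assert aris[2] <= aris[0]
        assert aris[2] < 0.8
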