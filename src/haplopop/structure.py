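"""Population structure, relatedness, and isolation by distance.

The structure surface is deliberately simple for a ten-sample haploid
dataset: PCA and k-means on the biallelic genotype matrix recover the
geographic lineages; allele-sharing relatedness (a Weir–Goudet-style
matching coefficient, rescaled so the mean off-diagonal value is zero)
is the genetic response for the isolation-by-distance test.  Geography
enters through WGS84 geodesic distances, with optional waypoint
routing so that trans-Beringian pairs are measured along the plausible
dispersal route across the Bering Strait rather than over the pole.
Distances are converted to distance-based Moran's eigenvector maps
(dbMEMs) and regressed against the leading principal components of
relatedness by redundancy analysis (RDA), with significance from a row
permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans

from .io_formats import MISSING, SiteMatrix

__all__ = [
    "GenotypeMatrix",
    "IBDTestResult",
    "genotype_matrix",
    "pca_genotypes",
    "cluster_samples",
    "allele_sharing_relatedness",
    "vincenty_km",
    "geodesic_matrix",
    "bering_strait_rule",
    "build_dbmem",
    "rda_ibd_test",
]

#: default waypoint for routing Eurasia–North America pairs (lat, lon)
BERING_WAYPOINT = (65.8, -169.6)


@dataclass
class GenotypeMatrix:
    """Samples × biallelic SNPs, haploid dosage coding {0, 1, -1 missing}."""

    samples: list[str]
    chroms: list[str]
    positions: np.ndarray
    matrix: np.ndarray  # int8, -1 = missing

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class IBDTestResult:
    r_squared: float
    adj_r_squared: float
    p_value: float
    n_permutations: int
    n_dbmem_axes: int
    n_response_components: int
    seed: int


def genotype_matrix(sites: SiteMatrix, samples: list[str] | None = None) -> GenotypeMatrix:
    """Biallelic SNP matrix for PCA/relatedness.

    Multiallelic SNPs are excluded here (they are retained for π);
    dosage 0 is the reference allele when observed, otherwise the
    lexicographically first allele.
    """
    ids = samples if samples is not None else list(sites.samples)
    sub = sites.alleles[:, sites.sample_index(ids)]
    cols, chroms, positions = [], [], []
    for i in range(sites.n_sites):
        row = sub[i]
        obs = sorted({int(a) for a in row if a != MISSING})
        if len(obs) != 2:
            continue
        ref = int(sites.ref[i])
        a0 = ref if ref in obs else obs[0]
        a1 = obs[0] if obs[1] == a0 else obs[1]
        col = np.full(len(ids), -1, dtype=np.int8)
        col[row == a0] = 0
        col[row == a1] = 1
        cols.append(col)
        chroms.append(sites.chrom_names[sites.chrom_index[i]])
        positions.append(int(sites.pos[i]))
    matrix = (
        np.column_stack(cols) if cols else np.empty((len(ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(ids, chroms, np.array(positions, dtype=np.int64), matrix)


def pca_genotypes(
    geno: GenotypeMatrix, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix: (scores, variance-explained fractions).

    Missing entries are imputed to the SNP mean; columns are centered
    and optionally scaled by sqrt(p(1-p)).  All-missing columns are
    dropped.
    """
    if len(geno.samples) < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = geno.matrix.astype(float)
    X[geno.matrix == -1] = np.nan
    keep = ~np.all(np.isnan(X), axis=0)
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 usable SNPs for PCA")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= col_mean
    if scale:
        p = col_mean
        sd = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        X /= sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    total = (X**2).sum()
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return scores, var_frac


def cluster_samples(
    scores: np.ndarray,
    k: int,
    var_frac: np.ndarray | None = None,
    min_variance: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """k-means on the leading PCs (those explaining >= min_variance together).

    Deterministic given ``seed``; best of 10 restarts by inertia.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > scores.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    if var_frac is not None:
        cum = np.cumsum(var_frac)
        n_pc = int(np.searchsorted(cum, min_variance) + 1)
        n_pc = min(max(n_pc, 1), scores.shape[1])
        X = scores[:, :n_pc]
    else:
        X = scores
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def allele_sharing_relatedness(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise allele-sharing relatedness β.

    M_ij is the matching fraction over co-genotyped SNPs;
    β_ij = (M_ij − M̄)/(1 − M̄) with M̄ the mean of M over all
    unordered pairs, so the average off-diagonal β is zero by
    construction and identical samples score 1.
    """
    n = len(geno.samples)
    X = geno.matrix
    M = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (X[i] >= 0) & (X[j] >= 0)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"samples {geno.samples[i]} and {geno.samples[j]} share no genotyped SNPs"
                )
            M[i, j] = M[j, i] = float((X[i, ok] == X[j, ok]).mean())
    tri = M[np.triu_indices(n, k=1)]
    m_bar = tri.mean()
    if m_bar >= 1.0:
        beta = np.ones((n, n))
    else:
        beta = (M - m_bar) / (1.0 - m_bar)
    np.fill_diagonal(beta, 1.0)
    return pd.DataFrame(beta, index=geno.samples, columns=geno.samples)


# ---------------------------------------------------------------------------
# geodesic distances (WGS84 Vincenty inverse)

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


def vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Ellipsoidal geodesic distance (km) between two points, WGS84.

    Vincenty's inverse formula; falls back to a spherical great circle
    on the (near-antipodal) non-convergent cases, which do not arise
    for Holarctic sampling locations.
    """
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    U1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat2)))
    L = math.radians(lon2 - lon1)
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sigma_m = (
            cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # near-antipodal: spherical fallback
        R = (2 * _WGS84_A + _WGS84_B) / 3
        d = math.acos(
            max(-1.0, min(1.0, sinU1 * sinU2 + cosU1 * cosU2 * math.cos(L)))
        )
        return R * d / 1000.0
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * A * (sigma - delta_sigma) / 1000.0


def bering_strait_rule(row_a: pd.Series, row_b: pd.Series) -> bool:
    """Route a pair via the Bering Strait iff exactly one sample is North American."""
    return (row_a["lineage"] == "NAmerica") != (row_b["lineage"] == "NAmerica")


def geodesic_matrix(
    metadata: pd.DataFrame,
    routing: list[tuple[Callable[[pd.Series, pd.Series], bool], tuple[float, float]]]
    | None = None,
) -> pd.DataFrame:
    """Pairwise geodesic distance matrix (km), with waypoint routing.

    ``routing`` is a list of (pair predicate, waypoint (lat, lon))
    rules; for a matching pair the distance is the sum of the two
    waypoint legs.  The default routes intercontinental
    Eurasia–North America pairs across the Bering Strait.
    """
    if routing is None:
        routing = [(bering_strait_rule, BERING_WAYPOINT)]
    ids = list(metadata["sample"])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = metadata.iloc[i], metadata.iloc[j]
            d = None
            for pred, (wlat, wlon) in routing:
                if pred(a, b):
                    d = vincenty_km(a["lat"], a["lon"], wlat, wlon) + vincenty_km(
                        wlat, wlon, b["lat"], b["lon"]
                    )
                    break
            if d is None:
                d = vincenty_km(a["lat"], a["lon"], b["lat"], b["lon"])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# dbMEM + RDA


def build_dbmem(
    distance: pd.DataFrame | np.ndarray, autocor: str = "positive"
) -> np.ndarray:
    """Distance-based Moran's eigenvector maps.

    The distance matrix is truncated at the longest minimum-spanning-
    tree edge t (entries > t replaced by 4t), Gower double-centered
    (−½ d*² centered by rows and columns), and eigen-decomposed;
    eigenvectors with eigenvalue above 1e-9 × the largest are
    candidates, scaled by the square root of their eigenvalue.  With
    ``autocor="positive"`` (the usual dbMEM convention) only axes whose
    Moran's I against the within-truncation-distance connectivity
    exceeds its null expectation −1/(n−1) are retained — these are the
    broad-scale spatial patterns; the remaining positive-eigenvalue
    axes describe fine-scale/negative autocorrelation and only dilute a
    regression at small n.  ``autocor="all"`` keeps every candidate.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("dbMEM needs at least 3 samples")
    mst = minimum_spanning_tree(D).toarray()
    t = mst.max()
    if t <= 0:
        raise ValueError("all points coincident; no dbMEM axes")
    Dstar = np.where(D <= t, D, 4 * t)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = A - row - col + A.mean()
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9 * vals.max()
    if autocor == "positive":
        W = ((D <= t) & (D > 0)).astype(float)
        w_sum = W.sum()
        for i in np.flatnonzero(keep):
            u = vecs[:, i] - vecs[:, i].mean()
            moran = n / w_sum * (u @ W @ u) / (u @ u)
            if moran <= -1.0 / (n - 1):
                keep[i] = False
    elif autocor != "all":
        raise ValueError("autocor must be 'positive' or 'all'")
    if not keep.any():
        raise ValueError("no retained dbMEM axes")
    return vecs[:, keep] * np.sqrt(vals[keep])


def rda_ibd_test(
    relatedness: pd.DataFrame | np.ndarray,
    dbmem: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    response_components: float = 0.9,
) -> IBDTestResult:
    """Isolation-by-distance test: RDA of relatedness PCs on dbMEMs.

    The response is the set of leading principal components of the
    relatedness matrix reaching ``response_components`` cumulative
    variance; R² is the fraction of response variance captured by
    least-squares on the dbMEM basis, and P is the one-sided
    permutation probability under random row permutation of the
    response (P ≥ 1/(1+n_perm) by construction).
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    R = np.asarray(relatedness, dtype=float)
    n = R.shape[0]
    X = np.asarray(dbmem, dtype=float)
    if X.shape[0] != n:
        raise ValueError("relatedness and dbMEM bases are not conformable")
    m = X.shape[1]
    if m >= n - 1:
        raise ValueError(f"saturated model: {m} predictors for {n} samples")
    # principal components of the (column-centered) relatedness matrix
    Rc = R - R.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Rc, full_matrices=False)
    var = s**2
    if var.sum() <= 0:
        raise ValueError("relatedness matrix has no variance")
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, response_components) + 1)
    Y = (U * s)[:, :k]

    Xc = X - X.mean(axis=0, keepdims=True)
    pinv = np.linalg.pinv(Xc)

    def r2(Yp: np.ndarray) -> float:
        Yc = Yp - Yp.mean(axis=0, keepdims=True)
        fit = Xc @ (pinv @ Yc)
        ss_tot = (Yc**2).sum()
        return float((fit**2).sum() / ss_tot) if ss_tot > 0 else 0.0

    obs = r2(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r2(Y[perm]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    adj = 1 - (1 - obs) * (n - 1) / (n - m - 1)
    return IBDTestResult(obs, adj, p, n_perm, m, k, seed)
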