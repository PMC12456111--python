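"""Geographic distances, Moran eigenvector maps and Mantel tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .genio import PopulationFrame

EARTH_RADIUS_KM = 6371.0088


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km, elementwise with broadcasting."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geo_distance_matrix(frame: PopulationFrame) -> np.ndarray:
    """Symmetric matrix of pairwise great-circle distances (km)."""
    return haversine_km(
        frame.lat[:, None], frame.lon[:, None], frame.lat[None, :], frame.lon[None, :]
    )


# ---------------------------------------------------------------------------
# Moran eigenvector maps (dbMEM flavour)
# ---------------------------------------------------------------------------


@dataclass
class MemBasis:
    """Orthonormal spatial eigenvectors with Moran's I diagnostics."""

    vectors: np.ndarray        # (n_pops, k), positive-eigenvalue set
    eigenvalues: np.ndarray
    moran_i: np.ndarray
    moran_p: np.ndarray
    truncation_km: float

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    def significant(self, alpha: float = 0.05, max_k: int | None = None) -> np.ndarray:
        """Columns with significantly positive spatial autocorrelation."""
        keep = np.flatnonzero((self.moran_i > 0) & (self.moran_p < alpha))
        if max_k is not None:
            keep = keep[:max_k]
        return self.vectors[:, keep]


def morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Moran's I of ``x`` under the (symmetric) weight matrix ``w``
    (zero diagonal)."""
    z = x - x.mean()
    s0 = w.sum()
    return len(x) / s0 * float(z @ w @ z) / float(z @ z)


def build_mems(
    frame: PopulationFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> MemBasis:
    """Distance-based MEMs: truncate the great-circle distance matrix at the
    longest minimum-spanning-tree edge, set distances beyond it to 4x the
    truncation, double-centre the squared distances (principal-coordinate
    step) and keep the positive-eigenvalue eigenvectors. Moran's I for each
    vector is permutation-tested against binary within-truncation
    connectivity.
    """
    if frame.n_pops < 4:
        raise ValueError("need at least 4 populations for MEMs")
    d = geo_distance_matrix(frame)
    off = d[np.triu_indices(frame.n_pops, 1)]
    if np.any(off == 0):
        raise ValueError("duplicate coordinates; MEM construction refused")
    mst = minimum_spanning_tree(d).toarray()
    trunc = float(mst.max())
    dt = np.where(d <= trunc, d, 4.0 * trunc)
    np.fill_diagonal(dt, 0.0)

    a = -0.5 * dt**2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    gower = j @ a @ j
    vals, vecs = np.linalg.eigh(gower)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > vals.max() * 1e-9
    vals, vecs = vals[pos], vecs[:, pos]

    w = ((d <= trunc) & (d > 0)).astype(float)
    rng = np.random.default_rng(seed)
    mi = np.array([morans_i(vecs[:, k], w) for k in range(vecs.shape[1])])
    pvals = np.empty(vecs.shape[1])
    for k in range(vecs.shape[1]):
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            null[b] = morans_i(rng.permutation(vecs[:, k]), w)
        pvals[k] = (1 + np.sum(null >= mi[k])) / (n_permutations + 1)
    return MemBasis(
        vectors=vecs, eigenvalues=vals, moran_i=mi, moran_p=pvals,
        truncation_km=trunc,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided (upper-tail) Mantel test.

    r is the Pearson correlation over the strictly lower triangles; the null
    is built by jointly permuting rows and columns of ``d2``;
    p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must share a square shape")
    n = d1.shape[0]
    il = np.tril_indices(n, -1)
    x = d1[il]
    if x.std() == 0 or d2[il].std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())

    def corr(mat: np.ndarray) -> float:
        y = mat[il]
        yc = y - y.mean()
        return float(xc @ yc) / (xnorm * np.sqrt((yc**2).sum()))

    r_obs = corr(d2)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(d2[np.ix_(perm, perm)]) >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_permutations + 1)
    return r_obs, p
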