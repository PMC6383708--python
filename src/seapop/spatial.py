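"""Between-site distances and spatial eigenfunctions (dbMEM/PCNM).

Spatial structure among sampling sites is decomposed into orthogonal
eigenvectors of a truncated distance matrix (the classical PCNM
construction): distances above a truncation threshold t (default: the
longest edge of the minimum spanning tree, which keeps the site graph
connected) are replaced by 4t, the matrix is Gower-centred, and the
positive-eigenvalue eigenvectors serve as multi-scale spatial predictors
in constrained ordination.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric site × site distance matrix in km with a source tag."""

    matrix: pd.DataFrame
    source: str = "great-circle"  # or "user-supplied marine"

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(m, 0.0)
        self.matrix = pd.DataFrame(m, index=self.matrix.index, columns=self.matrix.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.matrix.index)

    @classmethod
    def read_tsv(cls, path: str | Path, source: str = "user-supplied marine") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, source=source)

    def write_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t")


def greatcircle_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Haversine distances (km, Earth radius 6371 km) between sites.

    ``coords`` has one row per site with columns ``lat`` and ``lon`` in
    decimal degrees.
    """
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates out of range: |lat|<=90, |lon|<=180 required")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    return DistanceMatrix(pd.DataFrame(d, index=coords.index, columns=coords.index))


@dataclass
class DbMEMBasis:
    """Positive-eigenvalue spatial eigenvectors from a truncated distance matrix."""

    vectors: pd.DataFrame  # sites × axes, columns dbMEM1..k
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_axes(self) -> int:
        return self.vectors.shape[1]


def dbmem(
    dist: DistanceMatrix,
    truncation: float | None = None,
    positive_moran_only: bool = False,
    tol: float = 1e-9,
) -> DbMEMBasis:
    """Spatial eigenvectors by the PCNM construction.

    Entries above the truncation threshold t (default: longest edge of the
    minimum spanning tree) are set to 4t; the result is Gower-centred
    (−½ D*² double-centred) and eigen-decomposed. Axes with eigenvalue
    above ``tol`` (relative to the largest) are returned in decreasing
    eigenvalue order with a deterministic sign (largest-magnitude loading
    positive). ``positive_moran_only`` additionally drops axes whose
    Moran's I (with 1/d weights at retained edges) is non-positive — the
    stricter dbMEM screening.
    """
    m = dist.matrix.to_numpy(dtype=float)
    n = m.shape[0]
    if n < 3:
        raise ValueError("dbMEM needs at least 3 sites")
    off = m[np.triu_indices(n, 1)]
    if np.allclose(off, 0):
        raise ValueError("all between-site distances are zero")
    if truncation is None:
        mst = minimum_spanning_tree(m).toarray()
        truncation = float(mst.max())
    t = float(truncation)
    dstar = np.where(m <= t, m, 4 * t)
    np.fill_diagonal(dstar, 0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dstar**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(vals.max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    for k in range(vecs.shape[1]):
        v = vecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            vecs[:, k] = -v
    if positive_moran_only and vecs.shape[1] > 0:
        w = np.where((m > 0) & (m <= t), 1.0 / np.where(m > 0, m, 1.0), 0.0)
        keep2 = []
        for k in range(vecs.shape[1]):
            v = vecs[:, k] - vecs[:, k].mean()
            denom = (v**2).sum() * w.sum()
            moran = n * (w * np.outer(v, v)).sum() / denom if denom > 0 else 0.0
            keep2.append(moran > 0)
        vals, vecs = vals[keep2], vecs[:, keep2]
    cols = [f"dbMEM{k + 1}" for k in range(vecs.shape[1])]
    return DbMEMBasis(pd.DataFrame(vecs, index=dist.matrix.index, columns=cols), vals, t)
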