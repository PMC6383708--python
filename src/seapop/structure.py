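"""Population structure: imputation, UPGMA dendrogram, DAPC.

Missing genotypes are imputed by seeded draws from the empirical
genotype-class frequencies of the individual's differentiation-defined
group (see :func:`seapop.popstats.fst_groups`), which is unbiased for the
downstream frequency-based statistics. The UPGMA dendrogram is built on
pairwise θ (clamped at zero) with locus-bootstrap bipartition support, and
DAPC follows the usual PCA → k-means (BIC) / linear discriminant recipe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from seapop.geno_io import MISSING, GenotypeMatrix
from seapop.popstats import FstMatrix, _pop_locus_stats, wc_components


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    gm: GenotypeMatrix, groups: dict[str, int] | None = None, seed: int | None = None
) -> GenotypeMatrix:
    """Fill missing dosages by draws from group genotype-class frequencies.

    ``groups`` maps site -> group (default: every site its own group).
    Each missing call is drawn from the empirical {0,1,2} frequencies of
    its locus within the individual's group, falling back to the global
    frequencies when the group has no calls at that locus. Deterministic
    given ``seed``; the output contains no missing values.
    """
    if groups is None:
        groups = {s: i for i, s in enumerate(gm.sites)}
    missing_sites = [s for s in gm.sites if s not in groups]
    if missing_sites:
        raise ValueError(f"sites without a group: {missing_sites}")
    rng = np.random.default_rng(seed)
    d = gm.dosages.copy()
    called = d != MISSING
    no_calls = ~called.any(axis=0)
    if no_calls.any():
        ids = gm.loci["locus_id"][no_calls].tolist()
        raise ValueError(f"loci with no calls anywhere: {ids}")
    # global genotype-class frequencies as fallback
    gfreq = np.stack([(np.where(called, d, -9) == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)
    gfreq /= gfreq.sum(axis=0, keepdims=True)
    group_of_ind = np.array([groups[s] for s in gm.site_of_individual])
    for g in np.unique(group_of_ind):
        rows = np.flatnonzero(group_of_ind == g)
        sub = d[rows]
        subcalled = sub != MISSING
        counts = np.stack([(np.where(subcalled, sub, -9) == v).sum(axis=0) for v in (0, 1, 2)]).astype(float)
        tot = counts.sum(axis=0)
        freq = np.where(tot > 0, counts / np.where(tot > 0, tot, 1), gfreq)
        # draw all missing calls in this group at once via inverse CDF
        mi, mj = np.nonzero(~subcalled)
        if len(mi) == 0:
            continue
        cdf = np.cumsum(freq[:, mj], axis=0)
        u = rng.random(len(mi))
        draws = (u[None, :] > cdf).sum(axis=0)
        d[rows[mi], mj] = draws.astype(d.dtype)
    out = GenotypeMatrix(d, list(gm.individual_ids), gm.site_of_individual.copy(), gm.loci.copy(), gm.depth)
    return out


# ---------------------------------------------------------------------------
# UPGMA dendrogram


@dataclass
class Dendrogram:
    """Rooted ultrametric site tree in θ units with bootstrap supports."""

    sites: list[str]  # lexicographic leaf order used for tie-breaking
    linkage_matrix: np.ndarray
    heights: np.ndarray  # node heights (half the merge distances)
    supports: np.ndarray | None  # % per internal node, aligned with linkage rows
    r2: float
    newick: str


def _clusters_from_linkage(z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        members[n + k] = members[a] | members[b]
        out.append(members[n + k])
    return out


def _upgma_linkage(fst: FstMatrix) -> tuple[list[str], np.ndarray]:
    sites = sorted(fst.sites)  # lexicographic order fixes tie-breaking
    m = fst.theta.loc[sites, sites].to_numpy().copy()
    m = np.clip(m, 0, None)
    np.fill_diagonal(m, 0.0)
    z = linkage(squareform(m, checks=False), method="average")
    return sites, z


def upgma_tree(
    fst: FstMatrix,
    gm: GenotypeMatrix | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> Dendrogram:
    """UPGMA (average linkage) on pairwise θ, with optional locus bootstrap.

    Negative θ are clamped at 0 before clustering. When ``gm`` is given,
    ``n_boot`` locus resamples produce replicate trees; the support of each
    internal node is the percentage of replicates containing the same leaf
    cluster. Ties in merge order are broken by lexicographic site order.
    The Newick string carries supports as internal labels and heights in θ
    units (a pair at distance d joins at height d/2).
    """
    if len(fst.sites) < 3:
        raise ValueError("UPGMA needs at least 3 sites")
    sites, z = _upgma_linkage(fst)
    obs_clusters = _clusters_from_linkage(z, sites)

    supports = None
    if gm is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        order = [s for s in gm.sites]
        _, n, p, h = _pop_locus_stats(gm)
        S, L = n.shape
        pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
        A = np.zeros((len(pairs), L))
        D = np.zeros((len(pairs), L))
        for k, (i, j) in enumerate(pairs):
            a, b, c = wc_components(n[[i, j]], p[[i, j]], h[[i, j]])
            A[k] = np.nan_to_num(a)
            D[k] = np.nan_to_num(a + b + c)
        counts = np.zeros(len(obs_clusters))
        for _ in range(n_boot):
            idx = rng.integers(0, L, size=L)
            num = A[:, idx].sum(axis=1)
            den = D[:, idx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tvec = np.where(den != 0, num / den, 0.0)
            mat = np.zeros((S, S))
            for k, (i, j) in enumerate(pairs):
                mat[i, j] = mat[j, i] = max(tvec[k], 0.0)
            dfm = pd.DataFrame(mat, index=order, columns=order).loc[sites, sites]
            zb = linkage(squareform(dfm.to_numpy(), checks=False), method="average")
            rep = set(_clusters_from_linkage(zb, sites))
            for ci, cl in enumerate(obs_clusters):
                if cl in rep:
                    counts[ci] += 1
        supports = 100.0 * counts / n_boot

    heights = z[:, 2] / 2.0
    # goodness of fit of cophenetic to input distances
    dvec = squareform(np.clip(fst.theta.loc[sites, sites].to_numpy(), 0, None), checks=False)
    coph = cophenet(z)
    ss_res = ((dvec - coph) ** 2).sum()
    ss_tot = ((dvec - dvec.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    newick = _to_newick(z, sites, heights, supports)
    return Dendrogram(sites, z, heights, supports, float(r2), newick)


def _to_newick(z: np.ndarray, labels: list[str], heights: np.ndarray, supports) -> str:
    n = len(labels)
    height_of = {i: 0.0 for i in range(n)}
    node_str = {i: labels[i] for i in range(n)}
    for k, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        h = heights[k]
        la = h - height_of[a]
        lb = h - height_of[b]
        sup = "" if supports is None else f"{supports[k]:.0f}"
        node_str[n + k] = f"({node_str[a]}:{la:.6g},{node_str[b]}:{lb:.6g}){sup}"
        height_of[n + k] = h
    return node_str[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# DAPC


def _centered_pcs(gm: GenotypeMatrix, n_pcs: int, seed: int | None = None) -> np.ndarray:
    x = np.where(gm.dosages == MISSING, np.nan, gm.dosages).astype(float)
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x) - col_mean
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return pca.fit_transform(x)


def dapc_find_clusters(
    gm: GenotypeMatrix, max_k: int = 10, n_pcs: int | None = None, seed: int | None = None
) -> tuple[pd.Series, int, np.ndarray]:
    """k-means over retained PCs with BIC model choice.

    BIC(K) = n·ln(WSS_K/n) + K·ln(n) under the spherical-Gaussian k-means
    convention. ``n_pcs`` defaults to all principal components — for
    cluster search there is no reason to discard variation, and retaining
    few PCs concentrates noise along the leading axes, which biases the
    WSS decline toward spurious extra clusters. Returns (BIC curve indexed
    by K, best K, memberships at best K); the full curve is returned so an
    elbow can be inspected.
    """
    n = gm.n_individuals
    if max_k >= n:
        raise ValueError("max_k must be smaller than the number of individuals")
    if n_pcs is None:
        n_pcs = min(n - 1, gm.n_loci)
    pcs = _centered_pcs(gm, n_pcs, seed)
    bics = {}
    members = {}
    for k in range(1, max_k + 1):
        if k == 1:
            wss = ((pcs - pcs.mean(axis=0)) ** 2).sum()
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            lab = km.fit_predict(pcs)
            wss = km.inertia_
        bics[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        members[k] = lab
    curve = pd.Series(bics, name="BIC")
    best = int(curve.idxmin())
    return curve, best, members[best]


@dataclass
class DapcResult:
    labels: list[str]
    n_pcs: int
    ind_coords: np.ndarray  # individuals × discriminant functions
    posteriors: pd.DataFrame  # individuals × labels
    assigned: list[str]
    alpha_score: float | None
    alpha_curve: pd.Series | None


def _alpha_score(pcs: np.ndarray, y: np.ndarray, labels: list[str]) -> float:
    """Mean over groups of (leave-one-out reassignment rate − 1/K)."""
    k = len(labels)
    pred = np.empty(len(y), dtype=object)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            pred[i] = y[i]
            continue
        lda = LinearDiscriminantAnalysis(priors=np.full(len(np.unique(y[mask])), 1 / len(np.unique(y[mask]))))
        lda.fit(pcs[mask], y[mask])
        pred[i] = lda.predict(pcs[i : i + 1])[0]
    rates = []
    for lab in labels:
        sel = y == lab
        if sel.any():
            rates.append((pred[sel] == lab).mean() - 1 / k)
    return float(np.mean(rates))


def dapc(
    gm: GenotypeMatrix,
    labels: np.ndarray | list[str] | None = None,
    n_pcs: int | None = None,
    seed: int | None = None,
    alpha_grid: list[int] | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components with given labels.

    Dosages are centred, reduced by PCA, and fed to a linear discriminant
    analysis with equal priors; up to (K−1) discriminant functions.
    When ``n_pcs`` is None, the α-score — mean over groups of the
    leave-one-out reassignment rate minus 1/K — is maximized over
    ``alpha_grid`` to pick the retained-PC count (guards against retaining
    so many PCs that the discriminants overfit).
    """
    y = np.asarray(labels if labels is not None else gm.site_of_individual, dtype=object)
    uniq = sorted(set(y))
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least 2 labels")
    for lab in uniq:
        if (y == lab).sum() == 1:
            warnings.warn(f"label {lab!r} has a single individual")
    max_pcs = min(gm.n_individuals - 1, gm.n_loci)
    alpha_curve = None
    alpha = None
    if n_pcs is None:
        grid = alpha_grid or sorted({max(len(uniq) - 1, 2), 5, 10, 20, 40, max_pcs // 2})
        grid = [g for g in grid if g <= max_pcs]
        scores = {}
        for g in grid:
            pcs = _centered_pcs(gm, g, seed)
            scores[g] = _alpha_score(pcs, y, uniq)
        alpha_curve = pd.Series(scores, name="alpha_score")
        n_pcs = int(alpha_curve.idxmax())
        alpha = float(alpha_curve.max())
    if n_pcs < len(uniq) - 1:
        raise ValueError("n_pcs must be at least number of labels - 1")
    pcs = _centered_pcs(gm, n_pcs, seed)
    lda = LinearDiscriminantAnalysis(priors=np.full(len(uniq), 1 / len(uniq)))
    lda.fit(pcs, y)
    coords = lda.transform(pcs)
    post = pd.DataFrame(lda.predict_proba(pcs), columns=lda.classes_, index=gm.individual_ids)
    post = post[uniq]
    assigned = [post.columns[k] for k in np.argmax(post.to_numpy(), axis=1)]
    if alpha is None:
        alpha = _alpha_score(pcs, y, uniq)
    return DapcResult(uniq, n_pcs, coords, post, assigned, alpha, alpha_curve)
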