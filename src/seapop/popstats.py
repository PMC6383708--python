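"""Diversity and differentiation statistics.

Implements the Weir & Cockerham (1984) variance-component estimator θ of
F_ST (per-locus components a, b, c; multi-locus estimate as a ratio of
sums), pairwise θ matrices with percentile bootstrap confidence intervals
over loci and Benjamini–Hochberg FDR, per-site diversity (Ho, He, F_IS
with permutation interval, nucleotide diversity), CI-based site grouping,
hierarchical AMOVA on dosage distances, and Mantel isolation-by-distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seapop.geno_io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Weir–Cockerham components


def _pop_locus_stats(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-site per-locus sample size n, alt frequency p, observed het h."""
    sites = gm.sites
    S, L = len(sites), gm.n_loci
    n = np.zeros((S, L))
    p = np.zeros((S, L))
    h = np.zeros((S, L))
    for si, (_, ix) in enumerate(gm.site_indices().items()):
        d = gm.dosages[ix]
        called = d != MISSING
        ni = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        het = ((d == 1) & called).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[si] = ni
            p[si] = np.where(ni > 0, alt / (2 * ni), np.nan)
            h[si] = np.where(ni > 0, het / ni, np.nan)
    return sites, n, p, h


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components a, b, c.

    ``n, p, h`` are (r populations × L loci) arrays of sample sizes, allele
    frequencies and observed heterozygosities. Loci where any population has
    fewer than one genotyped individual, or where the mean sample size is 1,
    yield NaN components.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = (n < 1).any(axis=0) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def weir_cockerham_theta(gm: GenotypeMatrix) -> float:
    """Multi-locus θ over all sites: Σa / Σ(a+b+c) (ratio of sums)."""
    _, n, p, h = _pop_locus_stats(gm)
    a, b, c = wc_components(n, p, h)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


# ---------------------------------------------------------------------------
# pairwise FST with bootstrap


@dataclass
class FstMatrix:
    """Pairwise Weir–Cockerham θ between sites with bootstrap CIs.

    ``theta``, ``ci_low``, ``ci_high``, ``p``, ``p_fdr`` are symmetric
    site × site DataFrames with a zero diagonal (p diagonal = NaN).
    """

    sites: list[str]
    theta: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    p: pd.DataFrame
    p_fdr: pd.DataFrame
    n_boot: int

    def pair(self, a: str, b: str) -> dict:
        return {
            "theta": self.theta.loc[a, b],
            "ci_low": self.ci_low.loc[a, b],
            "ci_high": self.ci_high.loc[a, b],
            "p": self.p.loc[a, b],
            "p_fdr": self.p_fdr.loc[a, b],
        }

    def mean_offdiag(self) -> float:
        v = self.theta.to_numpy()
        iu = np.triu_indices(len(self.sites), 1)
        return float(np.nanmean(v[iu]))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.sites):
            for b in self.sites[i + 1 :]:
                rows.append(
                    {
                        "site_a": a,
                        "site_b": b,
                        "theta": self.theta.loc[a, b],
                        "ci_low": self.ci_low.loc[a, b],
                        "ci_high": self.ci_high.loc[a, b],
                        "p": self.p.loc[a, b],
                        "p_fdr": self.p_fdr.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def pairwise_fst(gm: GenotypeMatrix, n_boot: int = 5000, seed: int | None = None) -> FstMatrix:
    """Pairwise multi-locus θ with percentile bootstrap CIs over loci.

    The one-sided p per pair is the fraction of locus-bootstrap replicates
    with θ* ≤ 0 (floored at 1/(n_boot+1)); p-values are FDR-adjusted across
    pairs (Benjamini–Hochberg). ``n_boot=0`` skips resampling (point
    estimates only, CIs equal the point, p = NaN).
    """
    sites, n, p, h = _pop_locus_stats(gm)
    if len(sites) < 2:
        raise ValueError("pairwise FST needs at least 2 sites")
    rng = np.random.default_rng(seed)
    S = len(sites)
    theta = np.zeros((S, S))
    lo = np.zeros((S, S))
    hi = np.zeros((S, S))
    pv = np.full((S, S), np.nan)
    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    raw_p = []
    for i, j in pairs:
        a, b, c = wc_components(n[[i, j]], p[[i, j]], h[[i, j]])
        ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        if not ok.any():
            warnings.warn(f"no shared genotyped loci for pair {sites[i]}–{sites[j]}")
            theta[i, j] = theta[j, i] = np.nan
            raw_p.append(np.nan)
            continue
        av, dv = a[ok], (a + b + c)[ok]
        t = av.sum() / dv.sum() if dv.sum() != 0 else np.nan
        theta[i, j] = theta[j, i] = t
        if n_boot > 0:
            L = len(av)
            reps = np.empty(n_boot)
            chunk = max(1, min(n_boot, 20_000_000 // max(L, 1)))
            done = 0
            while done < n_boot:
                k = min(chunk, n_boot - done)
                idx = rng.integers(0, L, size=(k, L))
                num = av[idx].sum(axis=1)
                den = dv[idx].sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    reps[done : done + k] = np.where(den != 0, num / den, np.nan)
                done += k
            ql, qh = np.nanpercentile(reps, [2.5, 97.5])
            lo[i, j] = lo[j, i] = ql
            hi[i, j] = hi[j, i] = qh
            pval = max(np.mean(reps <= 0), 1.0 / (n_boot + 1))
            pv[i, j] = pv[j, i] = pval
            raw_p.append(pval)
        else:
            lo[i, j] = lo[j, i] = t
            hi[i, j] = hi[j, i] = t
            raw_p.append(np.nan)
    pf = np.full((S, S), np.nan)
    finite = [k for k, v in enumerate(raw_p) if np.isfinite(v)]
    if finite and n_boot > 0:
        adj = multipletests([raw_p[k] for k in finite], method="fdr_bh")[1]
        for k, q in zip(finite, adj):
            i, j = pairs[k]
            pf[i, j] = pf[j, i] = q
    def df(m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=sites, columns=sites)
    return FstMatrix(sites, df(theta), df(lo), df(hi), df(pv), df(pf), n_boot)


def fst_groups(fst: FstMatrix) -> dict[str, int]:
    """Group sites whose pairwise 95% CI includes zero (transitive closure).

    Returns site -> group index; connected components of the CI-includes-zero
    graph, singletons for ungrouped sites. Group indices follow site order.
    """
    g = nx.Graph()
    g.add_nodes_from(fst.sites)
    for i, a in enumerate(fst.sites):
        for b in fst.sites[i + 1 :]:
            if fst.ci_low.loc[a, b] <= 0 <= fst.ci_high.loc[a, b]:
                g.add_edge(a, b)
    comps = sorted(nx.connected_components(g), key=lambda c: min(fst.sites.index(s) for s in c))
    return {site: gi for gi, comp in enumerate(comps) for site in comp}


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityTable:
    """Per-site diversity summary; ``table`` has one row per site."""

    table: pd.DataFrame
    n_perm: int
    locus_length_bp: int

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def diversity(
    gm: GenotypeMatrix,
    n_perm: int = 10000,
    locus_length_bp: int = 90,
    seed: int | None = None,
) -> DiversityTable:
    """Per-site Ho, He, F_IS (with permutation interval) and nucleotide diversity.

    Ho is the mean heterozygote fraction over loci polymorphic within the
    site; He the mean small-sample-corrected expected heterozygosity
    2p̂q̂·2n/(2n−1) over the same loci. F_IS = 1 − ΣHo_l/ΣHe_l over loci
    (within-population Weir–Cockerham form); its interval re-centres the
    permutation spread (alleles shuffled among individuals within the site)
    on the point estimate. Pi is the mean per-locus average pairwise
    difference divided by ``locus_length_bp`` over all loci.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for site, ix in gm.site_indices().items():
        d = gm.dosages[ix]
        if len(ix) < 2:
            rows.append(
                {"site": site, "n": len(ix), "Ho": np.nan, "He": np.nan, "Fis": np.nan,
                 "Fis_low": np.nan, "Fis_high": np.nan, "Pi": np.nan,
                 "n_monomorphic": np.nan, "n_polymorphic": np.nan}
            )
            continue
        called = d != MISSING
        ni = called.sum(axis=0)
        usable = ni >= 2
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = np.where(ni > 0, alt / (2 * ni), np.nan)
            ho_l = np.where(ni > 0, ((d == 1) & called).sum(axis=0) / ni, np.nan)
            he_l = 2 * phat * (1 - phat) * (2 * ni) / np.maximum(2 * ni - 1, 1)
        poly = usable & (phat > 0) & (phat < 1)
        mono = usable & ~poly
        ho = float(np.nanmean(ho_l[poly])) if poly.any() else 0.0
        he = float(np.nanmean(he_l[poly])) if poly.any() else 0.0
        fis, fis_lo, fis_hi = _fis_with_interval(d[:, poly], n_perm, rng) if poly.any() else (np.nan,) * 3
        pi = float(np.nanmean(np.where(usable, np.nan_to_num(he_l, nan=0.0), np.nan))) / locus_length_bp
        rows.append(
            {"site": site, "n": len(ix), "Ho": ho, "He": he, "Fis": fis,
             "Fis_low": fis_lo, "Fis_high": fis_hi, "Pi": pi,
             "n_monomorphic": int(mono.sum()), "n_polymorphic": int(poly.sum())}
        )
    return DiversityTable(pd.DataFrame(rows).set_index("site"), n_perm, locus_length_bp)


def _fis_point(d: np.ndarray) -> float:
    called = d != MISSING
    ni = called.sum(axis=0)
    ok = ni >= 2
    if not ok.any():
        return np.nan
    alt = np.where(called, d, 0).sum(axis=0)
    p = alt[ok] / (2 * ni[ok])
    ho = ((d == 1) & called).sum(axis=0)[ok] / ni[ok]
    he = 2 * p * (1 - p) * (2 * ni[ok]) / (2 * ni[ok] - 1)
    she = he.sum()
    if she == 0:
        return np.nan
    return float(1 - ho.sum() / she)


def _fis_with_interval(d: np.ndarray, n_perm: int, rng: np.random.Generator) -> tuple[float, float, float]:
    """Point F_IS and an interval from re-pairing alleles within the site.

    Each permutation randomly re-pairs the called alleles at every locus
    (Hardy–Weinberg null for heterozygosity); the permutation spread is
    re-centred on the point estimate. He is permutation-invariant so only
    the Ho sum is recomputed.
    """
    point = _fis_point(d)
    if n_perm <= 0 or not np.isfinite(point):
        return point, np.nan, np.nan
    n, L = d.shape
    called = d != MISSING
    ni = called.sum(axis=0)
    ok = ni >= 2
    if not ok.any():
        return point, np.nan, np.nan
    dd = d[:, ok]
    calledk = called[:, ok]
    nk = ni[ok]
    alt = np.where(calledk, dd, 0).sum(axis=0)
    p = alt / (2 * nk)
    he_sum = (2 * p * (1 - p) * (2 * nk) / (2 * nk - 1)).sum()
    if he_sum == 0:
        return point, np.nan, np.nan
    # allele matrix (2n x L'): rows 2i, 2i+1 hold individual i's alleles;
    # missing entries get +inf sort keys so called alleles stack on top
    a = np.empty((2 * n, dd.shape[1]), dtype=np.int8)
    a[0::2] = (dd > 0) & calledk
    a[1::2] = dd > 1
    miss2 = np.repeat(~calledk, 2, axis=0)
    perm_vals = np.empty(n_perm)
    for b in range(n_perm):
        keys = rng.random(a.shape)
        keys[miss2] = np.inf
        idx = np.argsort(keys, axis=0, kind="stable")
        ap = np.take_along_axis(a, idx, axis=0)
        pair_called = np.arange(1, 2 * n, 2)[:, None] < (2 * nk)[None, :]
        het = ((ap[0::2] + ap[1::2]) == 1) & pair_called
        ho_sum = (het.sum(axis=0) / nk).sum()
        perm_vals[b] = 1 - ho_sum / he_sum
    spread = perm_vals - np.nanmean(perm_vals)
    lo, hi = np.nanpercentile(spread, [2.5, 97.5])
    return point, point + lo, point + hi


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Hierarchical AMOVA variance components and permutation F-statistics.

    Components: among groups (a), among populations within groups (b),
    among individuals within populations (c). ``f_ct`` = σa²/σtotal²,
    ``f_sc`` = σb²/(σb²+σc²), ``f_st_hier`` = (σa²+σb²)/σtotal².
    """

    sigma_a: float
    sigma_b: float
    sigma_c: float
    pct: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st_hier: float
    p_f_ct: float
    p_f_sc: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_groups", "among_pops_within_groups", "within_pops"],
                "sigma2": [self.sigma_a, self.sigma_b, self.sigma_c],
                "pct": list(self.pct),
                "F": [self.f_ct, self.f_sc, self.f_st_hier],
                "p": [self.p_f_ct, self.p_f_sc, np.nan],
            }
        )


def _allele_rows(gm: GenotypeMatrix) -> np.ndarray:
    """(2n × L) allele indicator matrix: rows 2i, 2i+1 are individual i's
    alleles (NaN where the genotype is missing).

    AMOVA sums of squares depend only on per-locus allele counts within
    each stratum, so the arbitrary pairing of alleles across loci does not
    affect the decomposition; working at the allele level keeps the
    variance components on the same scale as gene-level F-statistics
    (a dosage-vector analysis would double-weight the among-group term
    against the within-population term).
    """
    d = gm.dosages
    n = gm.n_individuals
    a = np.empty((2 * n, gm.n_loci))
    a[0::2] = np.where(d == MISSING, np.nan, (d > 0).astype(float))
    a[1::2] = np.where(d == MISSING, np.nan, (d > 1).astype(float))
    return a


def _pairwise_sq_euclid(x: np.ndarray, n_loci: int) -> np.ndarray:
    """Squared Euclidean distances between rows, pairwise-complete
    coordinates rescaled to the total locus count."""
    m = (~np.isnan(x)).astype(float)
    xz = np.nan_to_num(x)
    x2 = xz**2
    cross = xz @ xz.T
    si = x2 @ m.T
    lcomp = m @ m.T
    d2 = si + si.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(lcomp > 0, d2 * n_loci / lcomp, np.nan)
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_components(
    d2: np.ndarray, pop_idx: list[np.ndarray], group_of_pop: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Variance components and F_CT, F_SC from a squared-distance matrix."""
    N = d2.shape[0]
    P = len(pop_idx)
    groups = np.unique(group_of_pop)
    G = len(groups)

    def ssd(idx: np.ndarray) -> float:
        return d2[np.ix_(idx, idx)].sum() / (2 * len(idx))

    all_idx = np.arange(N)
    ssd_t = ssd(all_idx)
    ssd_wp = sum(ssd(ix) for ix in pop_idx)
    group_members = {
        g: np.concatenate([pop_idx[k] for k in range(P) if group_of_pop[k] == g]) for g in groups
    }
    ssd_wg = sum(ssd(ix) for ix in group_members.values())
    ssd_ag = ssd_t - ssd_wg
    ssd_ap = ssd_wg - ssd_wp

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    n_p = np.array([len(ix) for ix in pop_idx], dtype=float)
    n_g = np.array([len(group_members[g]) for g in groups], dtype=float)
    sum_np2_by_group = np.array(
        [sum(n_p[k] ** 2 for k in range(P) if group_of_pop[k] == groups[gi]) for gi in range(G)]
    )
    n1 = (N - (sum_np2_by_group / n_g).sum()) / max(df_ap, 1)
    n2 = ((sum_np2_by_group / n_g).sum() - (n_p**2).sum() / N) / max(df_ag, 1)
    n3 = (N - (n_g**2).sum() / N) / max(df_ag, 1)

    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = ((ssd_ap / df_ap) - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = ((ssd_ag / df_ag) - sigma_c - n2 * sigma_b) / n3 if df_ag > 0 else 0.0
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total if total != 0 else np.nan
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    return sigma_a, sigma_b, sigma_c, f_ct, f_sc


def amova(
    gm: GenotypeMatrix,
    pop_of_site: dict[str, str],
    group_of_pop: dict[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations / within populations).

    Squared Euclidean distances between allele rows (two per individual;
    see :func:`_allele_rows`), pairwise-complete loci rescaled. Permutation
    p-values: whole populations permuted among groups for F_CT; individuals
    (keeping their two alleles together) permuted among populations within
    their group for F_SC.
    """
    pops = sorted(set(pop_of_site.values()))
    missing_pops = [p for p in pops if p not in group_of_pop]
    if missing_pops:
        raise ValueError(f"populations without group: {missing_pops}")
    site_ix = gm.site_indices()
    ind_idx = []
    for p in pops:
        members = [site_ix[s] for s in pop_of_site if pop_of_site[s] == p and s in site_ix]
        if not members:
            raise ValueError(f"population {p} has no sampled individuals")
        ind_idx.append(np.concatenate(members))
    gop = np.array([group_of_pop[p] for p in pops], dtype=object)
    if len(np.unique(gop)) < 2:
        raise ValueError("AMOVA requires at least 2 groups")
    if len(ind_idx) == gm.n_individuals:
        raise ValueError("degenerate grouping: every individual its own population")

    def expand(ix: np.ndarray) -> np.ndarray:
        return np.stack([2 * ix, 2 * ix + 1], axis=1).ravel()

    pop_idx = [expand(ix) for ix in ind_idx]
    d2 = _pairwise_sq_euclid(_allele_rows(gm), gm.n_loci)
    sa, sb, sc, f_ct, f_sc = _amova_components(d2, pop_idx, gop)
    total = sa + sb + sc
    if total == 0:
        pct = (np.nan, np.nan, np.nan)
    else:
        pct = tuple(100 * v / total for v in (sa, sb, sc))
    f_st_hier = (sa + sb) / total if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    hits_ct = hits_sc = 0
    for _ in range(n_perm):
        # F_CT: permute population-to-group labels
        gperm = rng.permutation(gop)
        *_, f_ct_p, _ = _amova_components(d2, pop_idx, gperm)
        if np.isfinite(f_ct_p) and f_ct_p >= f_ct:
            hits_ct += 1
        # F_SC: shuffle individuals among populations within each group
        pop_idx_p = [ix.copy() for ix in pop_idx]
        for g in np.unique(gop):
            ks = [k for k in range(len(pops)) if gop[k] == g]
            if len(ks) < 2:
                continue
            pool = np.concatenate([ind_idx[k] for k in ks])
            pool = rng.permutation(pool)
            off = 0
            for k in ks:
                pop_idx_p[k] = expand(pool[off : off + len(ind_idx[k])])
                off += len(ind_idx[k])
        *_, f_sc_p = _amova_components(d2, pop_idx_p, gop)
        if np.isfinite(f_sc_p) and f_sc_p >= f_sc:
            hits_sc += 1
    p_ct = (1 + hits_ct) / (n_perm + 1) if n_perm > 0 else np.nan
    p_sc = (1 + hits_sc) / (n_perm + 1) if n_perm > 0 else np.nan
    return AmovaResult(sa, sb, sc, pct, f_ct, f_sc, f_st_hier, p_ct, p_sc, n_perm)


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance


@dataclass
class IbdResult:
    r: float
    p: float
    adj_r2: float
    n_perm: int
    linearized: bool


def mantel_ibd(
    fst: "FstMatrix",
    dist,
    n_perm: int = 9999,
    linearize: bool = False,
    seed: int | None = None,
) -> IbdResult:
    """Mantel test of pairwise θ against geographic distance.

    One-sided (positive association); p from joint row/column permutations
    of the distance matrix (the identity permutation is skipped). Also fits
    OLS θ ~ distance and reports the Ezekiel adjusted R², with optional
    θ/(1−θ) linearization.
    """
    from seapop.spatial import DistanceMatrix

    dmat = dist.matrix if isinstance(dist, DistanceMatrix) else pd.DataFrame(dist)
    sites = fst.sites
    if set(sites) != set(dmat.index):
        raise ValueError("site sets of FST and distance matrices differ")
    if len(sites) < 4:
        raise ValueError("Mantel permutation is degenerate with fewer than 4 sites")
    f = fst.theta.loc[sites, sites].to_numpy()
    if linearize:
        f = f / (1 - f)
    g = dmat.loc[sites, sites].to_numpy()
    iu = np.triu_indices(len(sites), 1)
    fv, gv = f[iu], g[iu]
    if np.std(fv) == 0 or np.std(gv) == 0:
        warnings.warn("constant matrix: Mantel r undefined")
        return IbdResult(np.nan, np.nan, np.nan, n_perm, linearize)
    r_obs = float(np.corrcoef(fv, gv)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    idx0 = np.arange(len(sites))
    for _ in range(n_perm):
        perm = rng.permutation(idx0)
        while np.array_equal(perm, idx0):
            perm = rng.permutation(idx0)
        gp = g[np.ix_(perm, perm)][iu]
        if np.corrcoef(fv, gp)[0, 1] >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    n = len(fv)
    r2 = r_obs**2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return IbdResult(r_obs, p, float(adj_r2), n_perm, linearize)
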