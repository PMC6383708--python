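"""Genotype I/O, quality filtering and LD pruning.

The central container is :class:`GenotypeMatrix`: an individuals × loci
matrix of alternate-allele dosages (0, 1, 2, or ``MISSING``) with a sampling
site label per individual and per-locus metadata (chromosome, 1-based
position, locus id, REF/ALT alleles). All downstream statistics operate on
this object.

Filtering follows the conventions of RADSeq population panels: per-site
call-rate with an "all but one site" rule, per-call read-depth, a global-OR-
local minor-allele-frequency rule, a heterozygosity ceiling to catch
collapsed paralogs, an individual missingness cap, duplicate-position
removal, and optional one-SNP-per-locus thinning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage. Reserved; never a valid genotype value.
MISSING: int = -1

LOCUS_COLUMNS = ["chrom", "pos", "locus_id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals × loci alt-allele dosage matrix with site labels.

    Parameters
    ----------
    dosages
        int8/int16 array, shape (n_individuals, n_loci), values in
        {0, 1, 2, MISSING}.
    individual_ids
        Sample names, length n_individuals.
    site_of_individual
        Sampling-site label per individual (non-empty strings).
    loci
        DataFrame with columns ``chrom, pos, locus_id, ref, alt``; one row
        per locus. (chrom, pos) pairs must be unique.
    depth
        Optional per-call read depth, same shape as ``dosages``.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    site_of_individual: np.ndarray
    loci: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.site_of_individual = np.asarray(self.site_of_individual, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.site_of_individual) != n:
            raise ValueError("site_of_individual length does not match dosage rows")
        if len(self.loci) != m:
            raise ValueError("loci table length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosages contain invalid values: {np.unique(self.dosages[bad])}")
        if any(s == "" or s is None for s in self.site_of_individual):
            raise ValueError("site labels must be non-empty")
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = self.loci.loc[dup.idxmax()]
            raise ValueError(f"duplicated (chrom, pos): {first['chrom']}:{first['pos']}")
        self.loci = self.loci.reset_index(drop=True)

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def sites(self) -> list[str]:
        """Unique site labels in order of first appearance."""
        return list(dict.fromkeys(self.site_of_individual))

    def site_indices(self) -> dict[str, np.ndarray]:
        """Map site label -> row indices of its individuals."""
        sites = np.asarray(self.site_of_individual)
        return {s: np.flatnonzero(sites == s) for s in self.sites}

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.individual_ids),
            self.site_of_individual.copy(),
            self.loci.iloc[idx].reset_index(drop=True),
            None if self.depth is None else self.depth[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx],
            [self.individual_ids[i] for i in idx],
            self.site_of_individual[idx],
            self.loci.copy(),
            None if self.depth is None else self.depth[idx],
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per locus over the given rows (NaN if no calls)."""
        d = self.dosages if rows is None else self.dosages[rows]
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def site_allele_frequencies(self) -> pd.DataFrame:
        """Site × locus alt-allele frequency table (sites as rows)."""
        rows = {s: self.allele_frequencies(ix) for s, ix in self.site_indices().items()}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class FilterReport:
    """Ordered per-step accounting of loci/individuals surviving each filter."""

    steps: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # (name, loci_before, loci_after, indiv_before, indiv_after)

    def add(self, name: str, lb: int, la: int, ib: int, ia: int) -> None:
        if la > lb or ia > ib:
            raise ValueError(f"filter step '{name}' increased counts")
        self.steps.append((name, lb, la, ib, ia))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["filter", "loci_before", "loci_after", "indiv_before", "indiv_after"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading


def _read_site_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("site map must have two columns: sample, site")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_genotypes(
    path: str | Path,
    site_map: str | Path | dict[str, str],
    *,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a VCF (GT field) or a dosage TSV into a :class:`GenotypeMatrix`.

    Heterozygous genotypes become dosage 1, hom-ref 0, hom-alt 2, uncalled
    ``MISSING``. ``on_multiallelic`` is one of ``"error"`` (default),
    ``"drop"``, or ``"split"`` (one pseudo-biallelic locus per ALT allele).

    ``site_map`` is a two-column TSV (sample, site) or an equivalent dict;
    every sample in the genotype file must appear in it.
    """
    path = Path(path)
    mapping = site_map if isinstance(site_map, dict) else _read_site_map(site_map)
    if path.suffix in (".tsv", ".txt"):
        gm = _read_dosage_tsv(path)
    else:
        gm = _read_vcf(path, on_multiallelic=on_multiallelic)
    unknown = [s for s in gm.individual_ids if s not in mapping]
    if unknown:
        raise ValueError(f"samples missing from site map: {', '.join(unknown)}")
    sites = np.array([mapping[s] for s in gm.individual_ids], dtype=object)
    return replace(gm, site_of_individual=sites)


def _read_vcf(path: Path, *, on_multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "drop", "split"):
        raise ValueError(f"unknown multiallelic policy: {on_multiallelic!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    meta: list[tuple] = []
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}")
            if on_multiallelic == "drop":
                continue
        alts = v.ALT if on_multiallelic == "split" else v.ALT[:1]
        gts = np.array(v.genotypes, dtype=object)  # [a1, a2, phased]
        a = np.array([g[0] for g in gts], dtype=int)
        b = np.array([g[1] for g in gts], dtype=int)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
        for k, alt in enumerate(alts, start=1):
            dos = np.where((a < 0) | (b < 0), MISSING, (a == k).astype(int) + (b == k).astype(int))
            cols.append(dos.astype(np.int8))
            depth_cols.append(
                np.full(len(samples), -1, dtype=np.int32) if dp is None else dp[:, 0].astype(np.int32)
            )
            lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
            if len(alts) > 1:
                lid = f"{lid}_alt{k}"
            meta.append((v.CHROM, v.POS, lid, v.REF, alt))
    if not meta:
        raise ValueError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(cols)
    loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS)
    if on_multiallelic == "split":
        # split records share a position; disambiguate to keep (chrom,pos) unique
        dup = loci.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            loci = loci.copy()
            offsets = loci.groupby(["chrom", "pos"]).cumcount()
            loci["pos"] = loci["pos"] + offsets  # pseudo-positions, documented
    depth = np.column_stack(depth_cols) if any_depth else None
    return GenotypeMatrix(dosages, samples, np.array(["?"] * len(samples), dtype=object), loci, depth)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    meta = []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) < 3:
            raise ValueError(f"dosage TSV column '{col}' is not chrom:pos:id")
        meta.append((parts[0], int(parts[1]), parts[2], "A", "T"))
    loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS)
    ids = [str(i) for i in df.index]
    return GenotypeMatrix(dosages, ids, np.array(["?"] * len(ids), dtype=object), loci)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV (rows=individuals, header chrom:pos:id)."""
    cols = [f"{r.chrom}:{r.pos}:{r.locus_id}" for r in gm.loci.itertuples()]
    df = pd.DataFrame(
        np.where(gm.dosages == MISSING, np.nan, gm.dosages),
        index=gm.individual_ids,
        columns=cols,
    )
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterParams:
    """Thresholds for :func:`filter_snps`; defaults follow common RADSeq practice."""

    call_rate: float = 0.80
    min_sites_call_rate: int | None = None  # default S-1
    depth_min: int = 5
    depth_mode: str = "per_call"  # or "per_snp_mean"
    maf_global: float = 0.01
    maf_local: float = 0.05
    het_max: float = 0.60
    min_sites_het: int | None = None  # default S-1
    indiv_missing_max: float = 0.12
    dedup_positions: bool = True
    one_snp_per_locus: bool = False


def _per_site_call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """site × locus fraction of called genotypes."""
    out = []
    for _, ix in gm.site_indices().items():
        out.append((gm.dosages[ix] != MISSING).mean(axis=0))
    return np.vstack(out)


def _per_site_het(gm: GenotypeMatrix) -> np.ndarray:
    """site × locus observed-heterozygosity among called genotypes (NaN if none)."""
    out = []
    for _, ix in gm.site_indices().items():
        d = gm.dosages[ix]
        called = (d != MISSING).sum(axis=0)
        het = (d == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append(np.where(called > 0, het / called, np.nan))
    return np.vstack(out)


def filter_snps(gm: GenotypeMatrix, params: FilterParams | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP and individual quality filters in order.

    Order: (1) call rate ≥ ``call_rate`` in at least S−1 sites; (2) read
    depth ≥ ``depth_min`` (low-depth calls set missing; skipped when no depth
    data); (3) global MAF ≥ ``maf_global`` OR local MAF ≥ ``maf_local`` in
    any site; (4) observed heterozygosity ≤ ``het_max`` in at least S−1
    sites; (5) drop individuals with more than ``indiv_missing_max`` missing;
    (6) drop duplicated (chrom, pos); (7) optionally keep the max-global-MAF
    SNP per locus_id.
    """
    p = params or FilterParams()
    sites = gm.sites
    if len(sites) < 2:
        raise ValueError("filtering requires at least 2 sampling sites")
    report = FilterReport()
    cur = gm

    def record(name: str, new: GenotypeMatrix) -> GenotypeMatrix:
        report.add(name, cur.n_loci, new.n_loci, cur.n_individuals, new.n_individuals)
        if new.n_loci == 0:
            raise ValueError(f"empty panel: all loci removed at step '{name}'")
        return new

    # 1. call rate in >= S-1 sites
    s_needed = p.min_sites_call_rate if p.min_sites_call_rate is not None else len(sites) - 1
    cr = _per_site_call_rate(cur)
    keep = (cr >= p.call_rate).sum(axis=0) >= s_needed
    cur = record("call_rate", cur.take_loci(np.flatnonzero(keep)))

    # 2. depth
    if cur.depth is not None:
        if p.depth_mode == "per_call":
            low = (cur.depth >= 0) & (cur.depth < p.depth_min)
            d = cur.dosages.copy()
            d[low] = MISSING
            cur2 = replace(cur, dosages=d)
            cur = record("depth_per_call", cur2)
        elif p.depth_mode == "per_snp_mean":
            dep = np.where(cur.depth >= 0, cur.depth, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_dep = np.nanmean(dep, axis=0)
            keep = ~(mean_dep < p.depth_min)
            cur = record("depth_per_snp_mean", cur.take_loci(np.flatnonzero(keep)))
        else:
            raise ValueError(f"unknown depth_mode: {p.depth_mode!r}")

    # 3. MAF: global OR local
    gfreq = cur.allele_frequencies()
    gmaf = np.minimum(gfreq, 1 - gfreq)
    site_f = cur.site_allele_frequencies().to_numpy()
    with np.errstate(invalid="ignore"):
        lmaf = np.nanmax(np.minimum(site_f, 1 - site_f), axis=0)
    keep = (gmaf >= p.maf_global) | (lmaf >= p.maf_local)
    keep &= ~np.isnan(gmaf)
    cur = record("maf", cur.take_loci(np.flatnonzero(keep)))

    # 4. heterozygosity ceiling in >= S-1 sites
    s_needed = p.min_sites_het if p.min_sites_het is not None else len(sites) - 1
    het = _per_site_het(cur)
    ok = np.where(np.isnan(het), True, het <= p.het_max)  # no-call site imposes no constraint
    keep = ok.sum(axis=0) >= s_needed
    cur = record("heterozygosity", cur.take_loci(np.flatnonzero(keep)))

    # 5. individual missingness
    miss = cur.missing_mask().mean(axis=1)
    keep_ind = np.flatnonzero(miss <= p.indiv_missing_max)
    cur = record("indiv_missing", cur.take_individuals(keep_ind))

    # 6. duplicated positions (container forbids them; step kept for TSV inputs
    # where pseudo-positions may collide after upstream edits)
    if p.dedup_positions:
        dup = cur.loci.duplicated(subset=["chrom", "pos"], keep=False)
        cur = record("dup_positions", cur.take_loci(np.flatnonzero(~dup.to_numpy())))

    # 7. one SNP per locus, max global MAF
    if p.one_snp_per_locus:
        gfreq = cur.allele_frequencies()
        gmaf = np.minimum(gfreq, 1 - gfreq)
        order = pd.DataFrame({"locus": cur.loci["locus_id"], "maf": gmaf})
        keep_idx = order.groupby("locus", sort=False)["maf"].idxmax().to_numpy()
        cur = record("one_snp_per_locus", cur.take_loci(np.sort(keep_idx)))

    return cur, report


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Composite-LD r² between dosage columns, pairwise-complete."""
    x = np.where(d == MISSING, np.nan, d).astype(float)
    m = x.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if ok.sum() < 3:
                continue
            xi, xj = x[ok, i], x[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.8, seed: int | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Iteratively remove one member of each within-chromosome pair with r² ≥ threshold.

    The removed member of each linked pair is chosen uniformly at random
    (seeded), matching the random-removal convention; pairs sharing a member
    are resolved as removal proceeds, so fewer SNPs than pairs are dropped.
    Returns the pruned matrix and the list of removed locus ids.
    """
    rng = np.random.default_rng(seed)
    removed_ids: list[str] = []
    keep_global = np.ones(gm.n_loci, dtype=bool)
    chroms = gm.loci["chrom"].to_numpy()
    for ch in pd.unique(chroms):
        idx = np.flatnonzero(chroms == ch)
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(gm.dosages[:, idx])
        alive = np.ones(len(idx), dtype=bool)
        while True:
            sub = r2[np.ix_(alive, alive)]
            ii, jj = np.where(np.triu(sub, 1) >= r2_max)
            if len(ii) == 0:
                break
            alive_idx = np.flatnonzero(alive)
            # resolve one pair at a time: random member of the first offending pair
            a, b = alive_idx[ii[0]], alive_idx[jj[0]]
            drop = a if rng.random() < 0.5 else b
            alive[drop] = False
        for k in np.flatnonzero(~alive):
            keep_global[idx[k]] = False
            removed_ids.append(str(gm.loci["locus_id"].iloc[idx[k]]))
    return gm.take_loci(np.flatnonzero(keep_global)), removed_ids


# ---------------------------------------------------------------------------
# identity-by-missingness diagnostic


def ibm_mds(gm: GenotypeMatrix, k: int = 2) -> np.ndarray:
    """Classical metric MDS of individuals on missingness-mismatch distances.

    A clustering of individuals here indicates genotyping batch effects
    (identity-by-missingness) rather than biology. Returns an
    n_individuals × k coordinate array; axes have the largest-magnitude
    loading positive.
    """
    if gm.n_individuals < 3:
        raise ValueError("IBM MDS needs at least 3 individuals")
    miss = gm.missing_mask().astype(float)
    # mismatch count = |m_i - m_j| summed over loci
    gram = miss @ miss.T
    row = miss.sum(axis=1)
    d2 = row[:, None] + row[None, :] - 2 * gram  # squared Euclidean on 0/1 = mismatch count
    if np.allclose(d2, 0):
        warnings.warn("all individuals share an identical missingness pattern")
        return np.zeros((gm.n_individuals, k))
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    coords = np.zeros((n, k))
    for ax, oi in enumerate(order[:k]):
        lam = max(vals[oi], 0.0)
        v = vecs[:, oi]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, ax] = v * np.sqrt(lam)
    return coords
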