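"""Synthetic seascape genotype–environment datasets with known truth.

Emulates a coastal RADSeq study system: sampling sites strung along a
quasi-linear coastline, hierarchical neutral population structure
(clusters of sites, Balding–Nichols drift at both levels), spatially
autocorrelated environmental fields, and a minority of adaptive loci whose
site allele frequencies follow logistic clines in one environmental
variable each. Genotypes are binomial draws from site frequencies with
missingness applied completely at random.

Because the truth (cluster labels, adaptive locus indices, effect signs) is
recorded, every downstream stage of the pipeline can be validated for
parameter recovery, null calibration and power without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seapop.geno_io import MISSING, LOCUS_COLUMNS, GenotypeMatrix

_EARTH_KM_PER_DEG_LAT = 111.32


@dataclass
class SimulationConfig:
    """Parameters of the synthetic seascape study.

    Defaults mirror a 13-site coastal survey of ~35 individuals per site,
    six latent clusters, 2,000 neutral biallelic SNPs on 10 chromosomes,
    mean pairwise differentiation near 0.009, ten environmental variables
    autocorrelated along a ~300 km coastline, and 4.7% missing genotypes.

    ``adaptive_effect`` is the slope of the logit site allele frequency per
    standard deviation of the assigned environmental variable.
    """

    n_sites: int = 13
    n_per_site: int | list[int] = 35
    n_clusters: int = 6
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 20
    fst_between_clusters: float = 0.006
    fst_within_cluster: float = 0.003
    env_n_vars: int = 10
    env_autocorr_range: float = 100.0  # km
    adaptive_effect: float = 2.0
    missing_rate: float = 0.047
    coastline_length_km: float = 300.0
    n_chromosomes: int = 10
    site_biased_missingness: float = 0.0  # extra missingness in odd-indexed sites
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_neutral_loci + self.n_adaptive_loci < 1:
            raise ValueError("degenerate config: need >=1 site and >=1 locus")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > 1 and self.n_sites < self.n_clusters:
            raise ValueError(
                f"cannot place {self.n_clusters} clusters over {self.n_sites} site(s)"
            )
        for name in ("fst_between_clusters", "fst_within_cluster", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1): got {v}")
        if self.fst_between_clusters < self.fst_within_cluster and self.n_clusters > 1:
            raise ValueError("fst_between_clusters must be >= fst_within_cluster")
        if self.n_adaptive_loci > 0 and self.env_n_vars < 1:
            raise ValueError("adaptive loci require at least one environmental variable")

    def per_site_counts(self) -> list[int]:
        if isinstance(self.n_per_site, int):
            return [self.n_per_site] * self.n_sites
        if len(self.n_per_site) != self.n_sites:
            raise ValueError("per-site count list length != n_sites")
        return list(self.n_per_site)


@dataclass
class SimulatedDataset:
    """A generated dataset plus its ground truth."""

    genotypes: GenotypeMatrix
    site_coords: pd.DataFrame  # index = site, columns lat/lon
    env: pd.DataFrame  # site × variable
    truth: dict = field(default_factory=dict)
    # truth keys: adaptive_loci (indices), adaptive_variable (per locus),
    # adaptive_sign (per locus), cluster_of_site (label -> cluster int)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant allele frequencies around ``p`` with divergence ``f``."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def _exp_gp(rng: np.random.Generator, positions: np.ndarray, rng_km: float, n_vars: int) -> np.ndarray:
    """Gaussian process draws (exponential covariance) over 1-D positions."""
    d = np.abs(positions[:, None] - positions[None, :])
    cov = np.exp(-d / max(rng_km, 1e-9)) + 1e-9 * np.eye(len(positions))
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((len(positions), n_vars))
    return chol @ z


def simulate_seascape(config: SimulationConfig) -> SimulatedDataset:
    """Generate a synthetic seascape dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counts = config.per_site_counts()
    n_sites = config.n_sites
    site_labels = [f"S{i + 1:02d}" for i in range(n_sites)]

    # --- geography: sites ordered along a 1-D coastline, mapped to lat/lon
    pos = np.sort(rng.uniform(0, config.coastline_length_km, size=n_sites))
    lat0, lon0 = 46.0, -64.5
    lat = lat0 + pos / _EARTH_KM_PER_DEG_LAT
    lon = np.full(n_sites, lon0) + rng.normal(0, 0.02, n_sites)  # jitter off the axis
    site_coords = pd.DataFrame({"lat": lat, "lon": lon}, index=site_labels)

    # --- clusters: contiguous blocks along the coast (every cluster non-empty)
    cluster_of_site = np.arange(n_sites) * config.n_clusters // n_sites

    # --- environment
    env_mat = _exp_gp(rng, pos, config.env_autocorr_range, config.env_n_vars)
    env = pd.DataFrame(
        env_mat, index=site_labels, columns=[f"env{j + 1}" for j in range(config.env_n_vars)]
    )
    env_std = (env_mat - env_mat.mean(axis=0)) / np.where(env_mat.std(axis=0) > 0, env_mat.std(axis=0), 1.0)

    # --- allele frequencies
    n_loci = config.n_neutral_loci + config.n_adaptive_loci
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    site_freq = np.empty((n_sites, n_loci))

    neutral = np.arange(config.n_neutral_loci)
    adaptive = np.arange(config.n_neutral_loci, n_loci)
    # neutral: cluster-level then site-level Balding–Nichols
    cluster_freq = np.empty((config.n_clusters, len(neutral)))
    for c in range(config.n_clusters):
        cluster_freq[c] = _balding_nichols(rng, p_anc[neutral], config.fst_between_clusters)
    for s in range(n_sites):
        site_freq[s, neutral] = _balding_nichols(
            rng, cluster_freq[cluster_of_site[s]], config.fst_within_cluster
        )
    # adaptive: logistic cline in the assigned variable (round-robin), random sign
    adaptive_variable = np.array([k % config.env_n_vars for k in range(len(adaptive))])
    adaptive_sign = rng.choice([-1, 1], size=len(adaptive))
    for k, locus in enumerate(adaptive):
        z = env_std[:, adaptive_variable[k]]
        logit = np.log(p_anc[locus] / (1 - p_anc[locus]))
        site_freq[:, locus] = 1.0 / (1.0 + np.exp(-(logit + adaptive_sign[k] * config.adaptive_effect * z)))

    # --- genotypes
    n_total = sum(counts)
    dosages = np.empty((n_total, n_loci), dtype=np.int8)
    sites_of_ind = np.empty(n_total, dtype=object)
    ids = []
    row = 0
    for s, label in enumerate(site_labels):
        n = counts[s]
        dosages[row : row + n] = rng.binomial(2, site_freq[s], size=(n, n_loci)).astype(np.int8)
        sites_of_ind[row : row + n] = label
        ids.extend(f"{label}_{i + 1:03d}" for i in range(n))
        row += n

    # --- missingness (MCAR; optional site-biased mode for the IBM diagnostic)
    miss_p = np.full(n_total, config.missing_rate)
    if config.site_biased_missingness > 0:
        odd = np.isin(sites_of_ind, [site_labels[i] for i in range(1, n_sites, 2)])
        miss_p = np.where(odd, np.minimum(miss_p + config.site_biased_missingness, 0.95), miss_p)
    if config.missing_rate > 0 or config.site_biased_missingness > 0:
        mask = rng.random((n_total, n_loci)) < miss_p[:, None]
        dosages[mask] = MISSING

    # --- locus metadata: spread over chromosomes in interleaved order so
    # neutral and adaptive loci share chromosomes
    order = rng.permutation(n_loci)
    chrom_of = np.empty(n_loci, dtype=object)
    pos_of = np.empty(n_loci, dtype=int)
    per_chrom: dict[int, int] = {}
    for rank, locus in enumerate(order):
        c = rank % config.n_chromosomes + 1
        per_chrom[c] = per_chrom.get(c, 0) + 1
        chrom_of[locus] = f"chr{c}"
        pos_of[locus] = per_chrom[c] * 1000
    loci = pd.DataFrame(
        {
            "chrom": chrom_of,
            "pos": pos_of,
            "locus_id": [f"L{i + 1:05d}" for i in range(n_loci)],
            "ref": "A",
            "alt": "T",
        }
    )[LOCUS_COLUMNS]

    gm = GenotypeMatrix(dosages, ids, sites_of_ind, loci)
    truth = {
        "adaptive_loci": adaptive.tolist(),
        "adaptive_locus_ids": [loci["locus_id"].iloc[i] for i in adaptive],
        "adaptive_variable": [f"env{v + 1}" for v in adaptive_variable],
        "adaptive_sign": adaptive_sign.tolist(),
        "cluster_of_site": {site_labels[s]: int(cluster_of_site[s]) for s in range(n_sites)},
    }
    return SimulatedDataset(gm, site_coords, env, truth)


# ---------------------------------------------------------------------------
# on-disk representation


def write_dataset(data: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write VCF + coordinate TSV + environment TSV + truth JSON.

    Returns a dict of artifact paths. The VCF (4.2, GT only) round-trips to
    an identical dosage matrix through :func:`seapop.geno_io.read_genotypes`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gm = data.genotypes
    paths = {
        "vcf": directory / "genotypes.vcf",
        "coords": directory / "site_coords.tsv",
        "env": directory / "environment.tsv",
        "truth": directory / "truth.json",
        "site_map": directory / "site_map.tsv",
    }
    _write_vcf(gm, paths["vcf"])
    data.site_coords.rename_axis("site").to_csv(paths["coords"], sep="\t")
    data.env.rename_axis("site").to_csv(paths["env"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        {"sample": gm.individual_ids, "site": gm.site_of_individual}
    ).to_csv(paths["site_map"], sep="\t", index=False)
    return paths


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    chroms = list(dict.fromkeys(gm.loci["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seapop-synthgen\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individual_ids) + "\n")
        # VCF convention: records sorted by contig then position
        order = gm.loci.sort_values(["chrom", "pos"], kind="stable").index
        for j in order:
            r = gm.loci.iloc[j]
            calls = "\t".join(_GT_CODE[int(v)] for v in gm.dosages[:, j])
            fh.write(f"{r.chrom}\t{r.pos}\t{r.locus_id}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{calls}\n")
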