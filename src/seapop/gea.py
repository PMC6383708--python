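"""Genotype–environment association from RDA loadings, and polygenic scores.

Candidate SNPs are those whose loading on a significant constrained axis
lies more than ``sd_cut`` standard deviations from the axis mean (the
loading-tail criterion). Each candidate is assigned to the environmental
variable it correlates with most strongly, and an unweighted additive
polygenic score per variable sums the candidates' dosages after orienting
each SNP so that its dosage increases with the variable. The score is
regressed on its variable with linear and quadratic OLS; the lower-AIC
model is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from seapop.geno_io import MISSING, GenotypeMatrix
from seapop.ordination import RdaModel


@dataclass
class OutlierSet:
    """Candidate SNPs flagged on significant RDA axes.

    ``table`` columns: locus_id, axis, loading, z. A SNP flagged on several
    axes keeps the axis of largest |z|. ``axis_stats`` records the mean and
    SD of loadings per axis; ``sd_cut`` the threshold used.
    """

    table: pd.DataFrame
    axis_stats: pd.DataFrame
    sd_cut: float

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table["locus_id"])


def rda_outliers(model: RdaModel, significant_axes: list[str], sd_cut: float = 3.0) -> OutlierSet:
    """Flag SNPs with |loading − mean| ≥ sd_cut·SD on any significant axis."""
    stats_rows = []
    hits: dict[str, tuple[str, float, float]] = {}
    if not significant_axes:
        warnings.warn("no significant axes: empty candidate set")
    for ax in significant_axes:
        if ax not in model.loadings.columns:
            raise ValueError(f"axis {ax!r} not in model loadings")
        load = model.loadings[ax]
        mu, sd = float(load.mean()), float(load.std(ddof=1))
        stats_rows.append({"axis": ax, "mean": mu, "sd": sd})
        if sd == 0:
            continue
        z = (load - mu) / sd
        for snp in load.index[np.abs(z) >= sd_cut]:
            zv = float(z.loc[snp])
            if snp not in hits or abs(zv) > abs(hits[snp][2]):
                hits[snp] = (ax, float(load.loc[snp]), zv)
    table = pd.DataFrame(
        [{"locus_id": s, "axis": a, "loading": l, "z": z} for s, (a, l, z) in hits.items()]
    )
    if table.empty:
        table = pd.DataFrame(columns=["locus_id", "axis", "loading", "z"])
    return OutlierSet(table.reset_index(drop=True), pd.DataFrame(stats_rows), sd_cut)


def _env_per_individual(gm: GenotypeMatrix, env: pd.DataFrame) -> pd.DataFrame:
    """Propagate site-level environment values to individuals."""
    missing = [s for s in gm.sites if s not in env.index]
    if missing:
        raise ValueError(f"sites without environmental values: {missing}")
    return env.loc[list(gm.site_of_individual)].set_index(pd.Index(gm.individual_ids))


def assign_candidates(
    outliers: OutlierSet, gm: GenotypeMatrix, env: pd.DataFrame
) -> pd.DataFrame:
    """Assign each candidate SNP to its best-correlated environmental variable.

    Site-level environment values are propagated to individuals; for each
    candidate the Pearson correlation of its dosage with every variable is
    computed on called genotypes, and the variable maximizing |r| wins
    (ties: lower variable index). Returns a frame with columns locus_id,
    variable, r. Zero-variance SNPs are dropped with a warning.
    """
    env_ind = _env_per_individual(gm, env).to_numpy(dtype=float)
    idx_of = {lid: j for j, lid in enumerate(gm.loci["locus_id"])}
    rows = []
    for lid in outliers.locus_ids:
        if lid not in idx_of:
            raise ValueError(f"candidate {lid!r} not in genotype matrix")
        d = gm.dosages[:, idx_of[lid]].astype(float)
        ok = d != MISSING
        dd = d[ok]
        if dd.std() == 0:
            warnings.warn(f"candidate {lid!r} has zero variance; dropped")
            continue
        best = None
        for v in range(env_ind.shape[1]):
            e = env_ind[ok, v]
            if e.std() == 0:
                continue
            r = float(np.corrcoef(dd, e)[0, 1])
            if best is None or abs(r) > abs(best[1]) + 1e-12:
                best = (v, r)
        if best is not None:
            rows.append({"locus_id": lid, "variable": env.columns[best[0]], "r": best[1]})
    return pd.DataFrame(rows, columns=["locus_id", "variable", "r"])


@dataclass
class PolygenicScoreTable:
    """Oriented additive polygenic scores and their environmental fits.

    ``scores``: individuals × variables integer scores in [0, 2k_v];
    ``fits``: per variable the selected model (linear/quadratic), both AIC
    values, adjusted R², model p, number of contributing SNPs and a
    low-support flag; ``orientations``: per SNP the sign applied.
    """

    scores: pd.DataFrame
    fits: pd.DataFrame
    orientations: pd.DataFrame = field(default_factory=pd.DataFrame)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood with constants dropped; constants cancel
    # between models fitted to the same data
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def polygenic_scores(
    gm: GenotypeMatrix,
    assignment: pd.DataFrame,
    env: pd.DataFrame,
    min_snps: int = 3,
) -> PolygenicScoreTable:
    """Per-variable additive polygenic scores with linear-vs-quadratic choice.

    For each SNP assigned to variable v, an OLS of dosage on v fixes the
    orientation: a negative slope recodes dosage d → 2−d so the score can
    only increase with v. The individual score is the sum of oriented
    dosages over the variable's SNP set. Score ~ v is then fitted with
    linear and quadratic OLS; the model with the lower AIC is selected.
    Input must be imputed (no missing dosages).
    """
    if (gm.dosages == MISSING).any():
        raise ValueError("missing genotypes present: impute before scoring")
    if assignment.empty:
        raise ValueError("empty candidate assignment")
    env_ind = _env_per_individual(gm, env)
    idx_of = {lid: j for j, lid in enumerate(gm.loci["locus_id"])}
    score_cols = {}
    fit_rows = []
    orient_rows = []
    for var, grp in assignment.groupby("variable", sort=False):
        e = env_ind[var].to_numpy(dtype=float)
        total = np.zeros(gm.n_individuals, dtype=int)
        for lid in grp["locus_id"]:
            d = gm.dosages[:, idx_of[lid]].astype(float)
            slope = np.polyfit(e, d, 1)[0] if e.std() > 0 else 0.0
            oriented = (2 - d) if slope < 0 else d
            orient_rows.append({"locus_id": lid, "variable": var, "flipped": bool(slope < 0)})
            total += oriented.astype(int)
        score_cols[var] = total
        xlin = sm.add_constant(e)
        xquad = sm.add_constant(np.column_stack([e, e**2]))
        mlin = sm.OLS(total, xlin).fit()
        mquad = sm.OLS(total, xquad).fit()
        aic_l = _aic(float(mlin.ssr), len(e), 2)
        aic_q = _aic(float(mquad.ssr), len(e), 3)
        best = mlin if aic_l <= aic_q else mquad
        fit_rows.append(
            {
                "variable": var,
                "model": "linear" if best is mlin else "quadratic",
                "aic_linear": aic_l,
                "aic_quadratic": aic_q,
                "adj_r2": float(best.rsquared_adj),
                "p": float(best.f_pvalue),
                "n_snps": len(grp),
                "low_support": len(grp) < min_snps,
            }
        )
    scores = pd.DataFrame(score_cols, index=gm.individual_ids)
    return PolygenicScoreTable(scores, pd.DataFrame(fit_rows).set_index("variable"), pd.DataFrame(orient_rows))
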