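"""Individual population assignment and Monte-Carlo migrant detection.

Frequency-based assignment in the Paetkau tradition: each individual's
multilocus genotype likelihood is evaluated under every reference unit's
allele frequencies (Hardy–Weinberg genotype probabilities, log10 summed
over loci), with the focal individual's alleles removed from its home unit
(leave-one-out). The home-likelihood criterion L_H flags putative migrants:
an individual whose L_H falls in the extreme lower tail of a Monte-Carlo
null of genotypes simulated from the home unit's frequencies is unlikely
to originate there, without requiring the true source to be sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from seapop.geno_io import MISSING, GenotypeMatrix


@dataclass
class AssignmentResult:
    """Per-individual likelihoods, assignments and (optional) migrant tests."""

    units: list[str]
    log10_lik: pd.DataFrame  # individuals × units
    table: pd.DataFrame  # individual, home, best, L_H, p, migrant
    confusion: pd.DataFrame  # home unit × best unit counts
    pct_correct: pd.Series  # per home unit, plus "overall"
    alpha: float | None = None

    @property
    def overall_correct(self) -> float:
        return float(self.pct_correct["overall"])


def _unit_of_individuals(gm: GenotypeMatrix, units) -> np.ndarray:
    if units is None:
        return np.asarray(gm.site_of_individual, dtype=object)
    if isinstance(units, dict):
        missing = [s for s in gm.sites if s not in units]
        if missing:
            raise ValueError(f"sites without a unit: {missing}")
        return np.array([units[s] for s in gm.site_of_individual], dtype=object)
    arr = np.asarray(units, dtype=object)
    if len(arr) != gm.n_individuals:
        raise ValueError("units vector length must match individuals")
    return arr


def _unit_counts(gm: GenotypeMatrix, unit_of: np.ndarray) -> tuple[list[str], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-unit per-locus alt-allele counts and called-genotype counts."""
    labels = list(dict.fromkeys(unit_of))
    alt: dict[str, np.ndarray] = {}
    ncall: dict[str, np.ndarray] = {}
    for u in labels:
        d = gm.dosages[unit_of == u]
        called = d != MISSING
        alt[u] = np.where(called, d, 0).sum(axis=0).astype(float)
        ncall[u] = called.sum(axis=0).astype(float)
    return labels, alt, ncall


def _log10_genotype_lik(d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-locus log10 HW genotype likelihood for dosage vector d (missing → 0)."""
    ok = d != MISSING
    q = 1 - p
    lp = np.select(
        [d == 0, d == 1, d == 2],
        [2 * np.log10(q), np.log10(2 * p * q), 2 * np.log10(p)],
        default=0.0,
    )
    return np.where(ok, lp, 0.0)


def assign_individuals(
    gm: GenotypeMatrix,
    units=None,
    freq_floor: float | None = None,
) -> AssignmentResult:
    """Leave-one-out frequency-based assignment of individuals to units.

    Reference alt-allele frequencies per unit are computed with the focal
    individual's alleles removed from its home unit; frequencies of 0 or 1
    are moved in by ``freq_floor`` (default 1/(2N_u+2)) so no genotype has
    zero likelihood. Missing loci are skipped per individual. The best unit
    maximizes the summed log10 likelihood.
    """
    unit_of = _unit_of_individuals(gm, units)
    labels, alt, ncall = _unit_counts(gm, unit_of)
    if len(labels) < 2:
        raise ValueError("assignment needs at least 2 units")
    for u in labels:
        if (unit_of == u).sum() == 1:
            warnings.warn(f"unit {u!r} has a single individual: home frequencies not leave-one-out")
    n = gm.n_individuals
    ll = np.full((n, len(labels)), np.nan)
    d_all = gm.dosages
    for uj, u in enumerate(labels):
        floor_u = freq_floor
        for i in range(n):
            d = d_all[i]
            called = d != MISSING
            a, m = alt[u].copy(), ncall[u].copy()
            if unit_of[i] == u and (unit_of == u).sum() > 1:
                a = a - np.where(called, d, 0)
                m = m - called
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(m > 0, a / (2 * m), np.nan)
            fl = floor_u if floor_u is not None else 1.0 / (2 * max((unit_of == u).sum(), 1) + 2)
            p = np.clip(p, fl, 1 - fl)
            usable = called & (m > 0)
            lp = _log10_genotype_lik(np.where(usable, d, MISSING), np.nan_to_num(p, nan=0.5))
            ll[i, uj] = lp.sum()
    lik = pd.DataFrame(ll, index=gm.individual_ids, columns=labels)
    best = [labels[k] for k in np.argmax(ll, axis=1)]
    lh = [ll[i, labels.index(unit_of[i])] for i in range(n)]
    table = pd.DataFrame(
        {
            "individual": gm.individual_ids,
            "home": unit_of,
            "best": best,
            "L_H": lh,
            "p": np.nan,
            "migrant": False,
        }
    )
    confusion = pd.crosstab(table["home"], table["best"]).reindex(
        index=labels, columns=labels, fill_value=0
    )
    per_unit = {}
    for u in labels:
        sel = table["home"] == u
        per_unit[u] = 100.0 * (table.loc[sel, "best"] == u).mean()
    per_unit["overall"] = 100.0 * (table["best"] == table["home"]).mean()
    return AssignmentResult(labels, lik, table, confusion, pd.Series(per_unit))


def migrant_test(
    gm: GenotypeMatrix,
    units=None,
    n_mc: int = 10000,
    alpha: float = 0.002,
    seed: int | None = None,
    freq_floor: float | None = None,
) -> AssignmentResult:
    """Monte-Carlo home-likelihood migrant test on top of assignment.

    Null home likelihoods are generated per unit by drawing, for each
    replicate and locus, two alleles without replacement from the unit's
    observed allele pool (hypergeometric dosage) and evaluating the
    resulting genotype under the leave-those-alleles-out frequencies —
    exactly the procedure applied to a real member, so resident p-values
    are uniform by exchangeability. Per individual the null sum runs over
    its called loci; p = (1 + #{null ≤ observed L_H}) / (n_mc + 1), and
    p < ``alpha`` flags a putative migrant.
    """
    if n_mc < 100:
        warnings.warn("n_mc < 100: migrant-test p-values have very coarse resolution")
    res = assign_individuals(gm, units, freq_floor)
    unit_of = _unit_of_individuals(gm, units)
    labels, alt, ncall = _unit_counts(gm, unit_of)
    rng = np.random.default_rng(seed)
    pvals = np.full(gm.n_individuals, np.nan)
    for u in labels:
        rows = np.flatnonzero(unit_of == u)
        nu = len(rows)
        fl = freq_floor if freq_floor is not None else 1.0 / (2 * nu + 2)
        a = alt[u]
        tot = 2 * ncall[u]
        usable = tot >= 4  # need a pool left after removing the replicate's alleles
        ag = a[usable].astype(np.int64)
        tg = tot[usable].astype(np.int64)
        # replicate dosages: 2 alleles drawn without replacement from the pool
        sims = rng.hypergeometric(ag, tg - ag, 2, size=(n_mc, ag.size))
        with np.errstate(invalid="ignore", divide="ignore"):
            p_rep = np.clip((ag - sims) / (tg - 2), fl, 1 - fl)
        contrib = np.select(
            [sims == 0, sims == 1, sims == 2],
            [2 * np.log10(1 - p_rep), np.log10(2 * p_rep * (1 - p_rep)), 2 * np.log10(p_rep)],
        )
        for i in rows:
            called = (gm.dosages[i] != MISSING)[usable]
            null = contrib[:, called].sum(axis=1)
            obs = res.table.loc[i, "L_H"]
            pvals[i] = (1 + np.sum(null <= obs)) / (n_mc + 1)
    res.table["p"] = pvals
    res.table["migrant"] = pvals < alpha
    res.alpha = alpha
    return res


def balanced_assignment(
    gm: GenotypeMatrix,
    units=None,
    n_per_unit: int | None = None,
    n_reps: int = 10,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean ± SD of overall leave-one-out accuracy over balanced subsamples.

    Each repetition draws ``n_per_unit`` individuals per unit (default: the
    smallest unit size) and re-runs the assignment, removing the bias that
    larger reference units attract assignments.
    """
    unit_of = _unit_of_individuals(gm, units)
    labels = list(dict.fromkeys(unit_of))
    sizes = {u: int((unit_of == u).sum()) for u in labels}
    smallest = min(sizes.values())
    if n_per_unit is None:
        n_per_unit = smallest
    if n_per_unit > smallest:
        raise ValueError(f"n_per_unit={n_per_unit} exceeds smallest unit size {smallest}")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        take = []
        for u in labels:
            rows = np.flatnonzero(unit_of == u)
            take.append(rng.choice(rows, size=n_per_unit, replace=False))
        idx = np.sort(np.concatenate(take))
        sub = gm.take_individuals(idx)
        sub_units = unit_of[idx]
        accs.append(assign_individuals(sub, sub_units).overall_correct)
    return float(np.mean(accs)), float(np.std(accs))
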