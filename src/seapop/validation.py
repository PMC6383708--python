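"""Recovery and calibration scenarios binding generator truth to pipeline output.

Each check simulates data with :mod:`seapop.synthgen` under a known truth
and verifies that the corresponding pipeline stage recovers it: the
differentiation estimator against its Balding–Nichols expectation, the
permutation tests against null uniformity, the RDA loading screen against
planted adaptive loci, the polygenic score against the planted effect
size, and assignment accuracy against the differentiation level. The
suite returns a JSON-serializable report with one pass/fail entry per
check; tolerances are fixed here, versioned with the code.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from seapop import assignment as assign_mod
from seapop import gea, ordination, popstats, synthgen


def check_fst_recovery(
    n_seeds: int = 20, target: float = 0.009, tol: float = 0.004, base_seed: int = 0
) -> dict:
    """Mean pairwise θ across seeds vs the simulated divergence level."""
    means = []
    for k in range(n_seeds):
        cfg = synthgen.SimulationConfig(
            n_sites=13, n_per_site=35, n_clusters=1, n_neutral_loci=2000,
            n_adaptive_loci=0, fst_between_clusters=target, fst_within_cluster=target,
            missing_rate=0.0, seed=base_seed + k,
        )
        data = synthgen.simulate_seascape(cfg)
        fst = popstats.pairwise_fst(data.genotypes, n_boot=0)
        means.append(fst.mean_offdiag())
    est = float(np.mean(means))
    return {"name": "fst_recovery", "value": est, "target": target,
            "tol": tol, "pass": bool(abs(est - target) <= tol)}


def _null_dataset(seed: int, n_sites: int = 6, n_per_site: int = 12, n_loci: int = 150):
    cfg = synthgen.SimulationConfig(
        n_sites=n_sites, n_per_site=n_per_site, n_clusters=1, n_neutral_loci=n_loci,
        n_adaptive_loci=0, fst_between_clusters=0.0, fst_within_cluster=0.0,
        missing_rate=0.0, adaptive_effect=0.0, seed=seed,
    )
    return synthgen.simulate_seascape(cfg)


def check_null_calibration(n_seeds: int = 200, base_seed: int = 1000, ks_alpha: float = 0.01) -> dict:
    """KS uniformity of RDA, AMOVA, Mantel and migrant-test null p-values."""
    rng = np.random.default_rng(base_seed)
    p_rda, p_amova, p_mantel, p_migr = [], [], [], []
    for k in range(n_seeds):
        seed = base_seed + k
        # RDA: site frequencies vs unrelated environment
        data = _null_dataset(seed)
        y = data.genotypes.site_allele_frequencies()
        x = rng.standard_normal((y.shape[0], 2))
        m = ordination.rda_fit(y, x)
        p_rda.append(ordination.rda_anova(m, "global", n_perm=99, seed=seed).table["p"].iloc[0])
        # Mantel: FST vs random distances
        fst = popstats.pairwise_fst(data.genotypes, n_boot=50, seed=seed)
        pts = rng.uniform(0, 100, size=(y.shape[0], 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dmat = pd.DataFrame(d, index=fst.sites, columns=fst.sites)
        p_mantel.append(popstats.mantel_ibd(fst, dmat, n_perm=99, seed=seed).p)
        # AMOVA: arbitrary grouping of panmictic sites; 8 populations in
        # unequal groups keep the permutation distribution fine-grained
        amova_data = _null_dataset(seed + 2 * 10**6, n_sites=8, n_per_site=8, n_loci=100)
        sites = amova_data.genotypes.sites
        pop_of_site = {s: s for s in sites}
        group_of_pop = {s: ("G0" if i < 3 else "G1") for i, s in enumerate(sites)}
        am = popstats.amova(amova_data.genotypes, pop_of_site, group_of_pop, n_perm=99, seed=seed)
        p_amova.append(am.p_f_ct)
        # migrant test: individuals genuinely from their own unit
        if k < n_seeds:
            small = _null_dataset(seed + 10**6, n_sites=2, n_per_site=10, n_loci=80)
            res = assign_mod.migrant_test(small.genotypes, n_mc=199, seed=seed)
            p_migr.append(float(res.table["p"].iloc[0]))
    out = {"name": "null_calibration", "components": {}}
    ok = True
    for label, ps in [("rda", p_rda), ("amova", p_amova), ("mantel", p_mantel), ("migrant", p_migr)]:
        ks = stats.kstest(ps, "uniform").pvalue
        out["components"][label] = {"ks_p": float(ks), "n": len(ps)}
        ok &= ks > ks_alpha
    out["pass"] = bool(ok)
    return out


def check_gea_operating_characteristics(
    n_seeds_fpr: int = 50, n_loci_fpr: int = 5000, base_seed: int = 2000
) -> dict:
    """±3 SD loading rule: false-positive rate under Gaussian loadings, and
    power to recover planted adaptive loci at a strong effect."""
    rng = np.random.default_rng(base_seed)
    flagged = 0
    total = 0
    for _ in range(n_seeds_fpr):
        load = rng.standard_normal(n_loci_fpr)
        z = (load - load.mean()) / load.std(ddof=1)
        flagged += int((np.abs(z) >= 3).sum())
        total += n_loci_fpr
    fpr = flagged / total
    expected = 2 * stats.norm.sf(3)
    se = np.sqrt(expected * (1 - expected) / total)
    fpr_ok = abs(fpr - expected) < 6 * se + 2e-4

    # power: strong planted clines
    cfg = synthgen.SimulationConfig(
        n_sites=13, n_per_site=20, n_clusters=1, n_neutral_loci=800, n_adaptive_loci=20,
        fst_between_clusters=0.003, fst_within_cluster=0.003, adaptive_effect=2.0,
        missing_rate=0.0, env_n_vars=4, seed=base_seed,
    )
    data = synthgen.simulate_seascape(cfg)
    gm = data.genotypes
    y = pd.DataFrame(gm.dosages.astype(float), index=gm.individual_ids,
                     columns=gm.loci["locus_id"])
    env_ind = data.env.loc[list(gm.site_of_individual)].set_index(y.index)
    model = ordination.rda_fit(y, env_ind)
    res = ordination.rda_anova(model, "axis", n_perm=99, seed=base_seed)
    sig = list(res.table.loc[res.table["p"] <= 0.05, "term"])
    outl = gea.rda_outliers(model, sig, sd_cut=3.0)
    truth = set(data.truth["adaptive_locus_ids"])
    found = set(outl.locus_ids)
    power = len(truth & found) / len(truth)
    neutral_flagged = len(found - truth)
    return {
        "name": "gea_operating_characteristics",
        "fpr": float(fpr), "fpr_expected": float(expected),
        "power": float(power), "n_false_positives": int(neutral_flagged),
        "pass": bool(fpr_ok and power >= 0.7),
    }


def check_polygenic_effect_response(base_seed: int = 3000) -> dict:
    """Polygenic-score adjusted R² increases with the planted effect size."""
    adj = []
    for effect in (0.0, 1.0, 2.5):
        cfg = synthgen.SimulationConfig(
            n_sites=10, n_per_site=20, n_clusters=1, n_neutral_loci=100,
            n_adaptive_loci=12, adaptive_effect=effect, env_n_vars=2,
            fst_between_clusters=0.003, fst_within_cluster=0.003,
            missing_rate=0.0, seed=base_seed,
        )
        data = synthgen.simulate_seascape(cfg)
        gm = data.genotypes
        assignment = pd.DataFrame(
            {"locus_id": data.truth["adaptive_locus_ids"],
             "variable": data.truth["adaptive_variable"]}
        )
        pst = gea.polygenic_scores(gm, assignment, data.env)
        adj.append(float(pst.fits["adj_r2"].mean()))
    increasing = adj[0] < adj[1] < adj[2]
    return {"name": "polygenic_effect_response", "adj_r2_by_effect": adj,
            "pass": bool(increasing)}


def check_assignment_vs_fst(base_seed: int = 4000) -> dict:
    """Leave-one-out assignment accuracy increases with differentiation."""
    accs = []
    for f in (0.002, 0.02, 0.1):
        cfg = synthgen.SimulationConfig(
            n_sites=4, n_per_site=20, n_clusters=1, n_neutral_loci=400,
            n_adaptive_loci=0, fst_between_clusters=f, fst_within_cluster=f,
            missing_rate=0.0, seed=base_seed,
        )
        data = synthgen.simulate_seascape(cfg)
        accs.append(assign_mod.assign_individuals(data.genotypes).overall_correct)
    return {"name": "assignment_vs_fst", "accuracy_by_fst": accs,
            "pass": bool(accs[0] < accs[1] < accs[2])}


def recovery_suite(seeds: int = 0, out: str | Path | None = None, quick: bool = False) -> dict:
    """Run all validation scenarios; optionally write the JSON report.

    ``quick`` trims replication counts for smoke runs. The report's
    ``pass`` is the conjunction of all checks.
    """
    report = {"checks": []}
    report["checks"].append(check_fst_recovery(n_seeds=5 if quick else 20, base_seed=seeds))
    report["checks"].append(check_null_calibration(n_seeds=40 if quick else 200, base_seed=seeds + 1000))
    report["checks"].append(
        check_gea_operating_characteristics(n_seeds_fpr=10 if quick else 50, base_seed=seeds + 2000)
    )
    report["checks"].append(check_polygenic_effect_response(base_seed=seeds + 3000))
    report["checks"].append(check_assignment_vs_fst(base_seed=seeds + 4000))
    report["pass"] = all(c["pass"] for c in report["checks"])
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=1))
    return report
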