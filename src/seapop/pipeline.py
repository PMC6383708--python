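"""End-to-end pipeline orchestration from a YAML config.

Stages run in the order: simulate (optional) → read/filter/LD-prune →
pairwise FST + CI grouping → imputation → diversity / AMOVA / IBD /
dendrogram / DAPC → distances + dbMEM → environmental screening +
stepwise RDA + variance partitioning → GEA outliers (optionally
intersected with user-supplied genome-scan outlier lists) → polygenic
scores → assignment + migrant test. Every stage writes its artifact under
the run directory plus a manifest (config hash, per-stage seed); stage
seeds derive deterministically from the master seed by stable hashing of
the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from seapop import assignment as assign_mod
from seapop import gea, geno_io, ordination, popstats, spatial, structure, synthgen

log = logging.getLogger("seapop")


@dataclass
class PipelineConfig:
    """All file paths, stage toggles and thresholds of a pipeline run."""

    # inputs (ignored when simulate=True)
    genotypes: str | None = None
    site_map: str | None = None
    coords: str | None = None
    env: str | None = None
    distance_matrix: str | None = None  # optional marine distances TSV
    external_outlier_lists: list[str] = field(default_factory=list)
    min_outlier_methods: int = 3

    simulate: bool = False
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    # thresholds
    call_rate: float = 0.80
    depth_min: int = 5
    maf_global: float = 0.01
    maf_local: float = 0.05
    het_max: float = 0.60
    indiv_missing_max: float = 0.12
    ld_r2_max: float = 0.8
    n_boot_fst: int = 5000
    n_boot_tree: int = 1000
    n_perm: int = 1000
    n_mc_assign: int = 10000
    sd_cut: float = 3.0
    migrant_alpha: float = 0.002
    vif_max: float = 10.0
    screen_p: float = 0.1
    corr_prune: float = 0.7
    dapc_max_k: int = 10
    gea_response: str = "individual"  # or "site"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 < self.call_rate <= 1, "call_rate must be in (0,1]"),
            (0 <= self.maf_global <= 0.5, "maf_global must be in [0,0.5]"),
            (0 <= self.maf_local <= 0.5, "maf_local must be in [0,0.5]"),
            (0 < self.het_max <= 1, "het_max must be in (0,1]"),
            (0 <= self.indiv_missing_max <= 1, "indiv_missing_max must be in [0,1]"),
            (0 < self.ld_r2_max <= 1, "ld_r2_max must be in (0,1]"),
            (0 < self.migrant_alpha < 1 or self.migrant_alpha == 0, "alpha must be in [0,1)"),
            (self.sd_cut > 0, "sd_cut must be positive"),
            (self.gea_response in ("individual", "site"), "gea_response must be individual|site"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        if not self.simulate:
            for name in ("genotypes", "site_map", "coords", "env"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"invalid config: input file for '{name}' missing: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed and stage name."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages; returns the run directory. Fails fast with stage name."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()

    def done(stage: str, **extra) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage), **extra}
        log.info("stage %s done %s", stage, extra)

    try:
        stage = "simulate"
        if config.simulate:
            sim_cfg = synthgen.SimulationConfig(
                **{"seed": stage_seed(config.seed, stage), **config.simulation}
            )
            data = synthgen.simulate_seascape(sim_cfg)
            paths = synthgen.write_dataset(data, out / "simulated")
            gm = data.genotypes
            coords, env = data.site_coords, data.env
            done(stage, n_individuals=gm.n_individuals, n_loci=gm.n_loci)
        else:
            gm = geno_io.read_genotypes(config.genotypes, config.site_map)
            coords = pd.read_csv(config.coords, sep="\t", index_col=0)
            env = pd.read_csv(config.env, sep="\t", index_col=0)
            done("read", n_individuals=gm.n_individuals, n_loci=gm.n_loci)

        stage = "filter"
        params = geno_io.FilterParams(
            call_rate=config.call_rate,
            depth_min=config.depth_min,
            maf_global=config.maf_global,
            maf_local=config.maf_local,
            het_max=config.het_max,
            indiv_missing_max=config.indiv_missing_max,
        )
        gm, report = geno_io.filter_snps(gm, params)
        report.write_tsv(out / "filter_report.tsv")
        gm, removed = geno_io.ld_prune(gm, config.ld_r2_max, stage_seed(config.seed, "ld"))
        (out / "ld_removed.txt").write_text("\n".join(removed))
        done(stage, n_loci=gm.n_loci, ld_removed=len(removed))

        stage = "fst"
        fst = popstats.pairwise_fst(gm, config.n_boot_fst, stage_seed(config.seed, stage))
        fst.to_long().to_csv(out / "fst_pairwise.tsv", sep="\t", index=False)
        fst.theta.to_csv(out / "fst_square.tsv", sep="\t")
        groups = popstats.fst_groups(fst)
        pd.Series(groups, name="group").rename_axis("site").to_csv(out / "fst_groups.tsv", sep="\t")
        done(stage, mean_theta=fst.mean_offdiag(), n_groups=len(set(groups.values())))

        stage = "impute"
        gm_imp = structure.impute_missing(gm, groups, stage_seed(config.seed, stage))
        done(stage)

        stage = "diversity"
        div = popstats.diversity(gm_imp, n_perm=min(config.n_perm, 200), seed=stage_seed(config.seed, stage))
        div.write_tsv(out / "diversity.tsv")
        done(stage)

        stage = "structure"
        tree = structure.upgma_tree(fst, gm_imp, config.n_boot_tree, stage_seed(config.seed, "tree"))
        (out / "upgma.nwk").write_text(tree.newick + "\n")
        curve, best_k, members = structure.dapc_find_clusters(
            gm_imp, max_k=min(config.dapc_max_k, gm_imp.n_individuals - 1),
            seed=stage_seed(config.seed, "dapc"),
        )
        curve.rename_axis("K").to_csv(out / "dapc_bic.tsv", sep="\t")
        pd.DataFrame(
            {"individual": gm_imp.individual_ids, "cluster": members}
        ).to_csv(out / "dapc_clusters.tsv", sep="\t", index=False)
        # cluster label per site = majority cluster of its individuals
        memb = pd.DataFrame({"site": gm_imp.site_of_individual, "cluster": members})
        cluster_of_site = memb.groupby("site")["cluster"].agg(lambda s: s.mode().iloc[0]).to_dict()
        done(stage, best_k=best_k, tree_r2=tree.r2)

        stage = "amova"
        pop_of_site = {s: f"P{groups[s]}" for s in gm_imp.sites}
        group_of_pop = {}
        for s in gm_imp.sites:
            group_of_pop.setdefault(pop_of_site[s], f"G{cluster_of_site[s]}")
        amova_res = None
        if len(set(group_of_pop.values())) >= 2 and len(set(pop_of_site.values())) > len(set(group_of_pop.values())):
            amova_res = popstats.amova(
                gm_imp, pop_of_site, group_of_pop, min(config.n_perm, 500), stage_seed(config.seed, stage)
            )
            amova_res.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
            done(stage, f_ct=amova_res.f_ct)
        else:
            done(stage, skipped="degenerate grouping")

        stage = "spatial"
        if config.distance_matrix:
            dist = spatial.DistanceMatrix.read_tsv(config.distance_matrix)
        else:
            dist = spatial.greatcircle_distances(coords)
        dist.write_tsv(out / "distances.tsv")
        mem = spatial.dbmem(dist)
        mem.vectors.to_csv(out / "dbmem.tsv", sep="\t")
        ibd = popstats.mantel_ibd(fst, dist, n_perm=min(config.n_perm * 10, 9999),
                                  seed=stage_seed(config.seed, "ibd"))
        (out / "ibd.json").write_text(json.dumps(
            {"mantel_r": ibd.r, "p": ibd.p, "adj_r2": ibd.adj_r2}, indent=1))
        done(stage, n_dbmem=mem.n_axes, mantel_r=ibd.r)

        stage = "rda"
        site_freq = gm_imp.site_allele_frequencies()
        env_sites = env.loc[site_freq.index]
        mem_sites = mem.vectors.loc[site_freq.index]
        retained = ordination.screen_variables(
            site_freq, env_sites, config.screen_p, config.corr_prune, config.vif_max,
            n_perm=min(config.n_perm, 499), seed=stage_seed(config.seed, "screen"),
        )
        x_full = pd.concat([env_sites[retained], mem_sites], axis=1)
        selected = ordination.ordistep(
            site_freq, x_full, n_perm=min(config.n_perm, 199),
            seed=stage_seed(config.seed, "ordistep"),
        )
        sel_env = [v for v in selected if v in retained]
        sel_spa = [v for v in selected if v not in retained]
        rda_report = {"screened": retained, "selected": selected}
        if sel_env and sel_spa:
            vp = ordination.varpart(
                site_freq, env_sites[sel_env], mem_sites[sel_spa],
                n_perm=min(config.n_perm, 499), seed=stage_seed(config.seed, "varpart"),
            )
            rda_report["varpart"] = {
                "env_unique": vp.env_unique, "joint": vp.joint,
                "spa_unique": vp.spa_unique, "residual": vp.residual,
                "p_env_unique": vp.p_env_unique, "p_spa_unique": vp.p_spa_unique,
                "p_global": vp.p_global,
            }
        if selected:
            m_sel = ordination.rda_fit(site_freq, x_full[selected])
            rda_report["global"] = {"r2": m_sel.r2, "adj_r2": m_sel.adj_r2}
        (out / "rda.json").write_text(json.dumps(rda_report, indent=1))
        done(stage, selected=selected)

        stage = "gea"
        if config.gea_response == "site":
            y_gea = site_freq
            env_for_fit = env_sites
        else:
            y_gea = pd.DataFrame(
                np.asarray(gm_imp.dosages, dtype=float),
                index=gm_imp.individual_ids, columns=gm_imp.loci["locus_id"],
            )
            env_for_fit = env.loc[list(gm_imp.site_of_individual)].set_index(y_gea.index)
        model = ordination.rda_fit(y_gea, env_for_fit)
        axis_res = ordination.rda_anova(model, by="axis", n_perm=min(config.n_perm, 199),
                                        seed=stage_seed(config.seed, "gea_axes"))
        sig_axes = list(axis_res.table.loc[axis_res.table["p"] <= 0.05, "term"])
        outliers = gea.rda_outliers(model, sig_axes, config.sd_cut)
        if config.external_outlier_lists:
            counts: dict[str, int] = {}
            for path in config.external_outlier_lists:
                for lid in Path(path).read_text().split():
                    counts[lid] = counts.get(lid, 0) + 1
            external = {l for l, c in counts.items() if c >= config.min_outlier_methods}
            keep = outliers.table["locus_id"].isin(external)
            outliers = gea.OutlierSet(outliers.table[keep].reset_index(drop=True),
                                      outliers.axis_stats, outliers.sd_cut)
        cand = gea.assign_candidates(outliers, gm_imp, env)
        merged = outliers.table.merge(cand, on="locus_id", how="left")
        merged.to_csv(out / "gea_outliers.tsv", sep="\t", index=False)
        done(stage, n_candidates=len(cand), sig_axes=sig_axes)

        stage = "polygenic"
        if len(cand):
            pst = gea.polygenic_scores(gm_imp, cand, env)
            pst.scores.rename_axis("individual").to_csv(out / "polygenic_scores.tsv", sep="\t")
            pst.fits.to_csv(out / "polygenic_fits.tsv", sep="\t")
            done(stage, n_variables=pst.scores.shape[1])
        else:
            done(stage, skipped="no candidates")

        stage = "assign"
        res = assign_mod.migrant_test(
            gm_imp, None, n_mc=config.n_mc_assign, alpha=config.migrant_alpha,
            seed=stage_seed(config.seed, stage),
        )
        res.table.to_csv(out / "assignment.tsv", sep="\t", index=False)
        res.confusion.to_csv(out / "assignment_confusion.tsv", sep="\t")
        done(stage, overall_correct=res.overall_correct,
             n_migrants=int(res.table["migrant"].sum()))
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
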