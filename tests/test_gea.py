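"""RDA-loading outlier detection, candidate assignment and polygenic scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seapop.gea import assign_candidates, polygenic_scores, rda_outliers
from seapop.ordination import RdaModel, rda_anova, rda_fit
from tests.conftest import make_gm


def model_with_loadings(loadings: pd.DataFrame) -> RdaModel:
    k = loadings.shape[1]
    return RdaModel(
        eigenvalues=np.ones(k), row_scores=np.zeros((2, k)), loadings=loadings,
        biplot_scores=pd.DataFrame(np.zeros((1, k)), columns=loadings.columns),
        r2=0.5, adj_r2=0.4, rank_x=1, n=10,
    )


class TestRdaOutliers:
    def test_gaussian_loadings_tail_fraction(self):
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(30):
            load = pd.DataFrame({"RDA1": rng.standard_normal(5000)},
                                index=[f"L{i}" for i in range(5000)])
            out = rda_outliers(model_with_loadings(load), ["RDA1"], sd_cut=3.0)
            fracs.append(len(out.table) / 5000)
        expected = 2 * stats.norm.sf(3)  # ≈ 0.0027
        assert np.mean(fracs) == pytest.approx(expected, abs=0.001)

    def test_injected_extreme_snp_flagged(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(1000) * 0.01
        vals[7] = vals.mean() + 5 * vals.std()
        load = pd.DataFrame({"RDA1": vals}, index=[f"L{i}" for i in range(1000)])
        out = rda_outliers(model_with_loadings(load), ["RDA1"])
        assert "L7" in out.locus_ids

    def test_multi_axis_keeps_largest_z(self):
        load = pd.DataFrame(
            {"RDA1": [0.0] * 99 + [5.0], "RDA2": [0.0] * 99 + [9.0]},
            index=[f"L{i}" for i in range(100)],
        )
        # inject spread so SD is nonzero on both axes
        rng = np.random.default_rng(2)
        load.iloc[:99, 0] = rng.standard_normal(99) * 0.1
        load.iloc[:99, 1] = rng.standard_normal(99) * 0.1
        out = rda_outliers(model_with_loadings(load), ["RDA1", "RDA2"])
        row = out.table.set_index("locus_id").loc["L99"]
        assert row["axis"] == "RDA2"

    def test_no_significant_axes_empty_with_notice(self):
        load = pd.DataFrame({"RDA1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            out = rda_outliers(model_with_loadings(load), [])
        assert out.table.empty

    def test_truth_recovery_on_planted_clines(self, adaptive_dataset):
        gm = adaptive_dataset.genotypes
        y = pd.DataFrame(gm.dosages.astype(float), index=gm.individual_ids,
                         columns=gm.loci["locus_id"])
        env_ind = adaptive_dataset.env.loc[list(gm.site_of_individual)].set_index(y.index)
        model = rda_fit(y, env_ind)
        res = rda_anova(model, "axis", n_perm=99, seed=1)
        sig = list(res.table.loc[res.table["p"] <= 0.05, "term"])
        out = rda_outliers(model, sig, sd_cut=3.0)
        truth = set(adaptive_dataset.truth["adaptive_locus_ids"])
        found = set(out.locus_ids)
        assert len(truth & found) / len(truth) >= 0.7
        # false positives stay near the nominal tail expectation
        n_neutral = gm.n_loci - len(truth)
        fp_rate = len(found - truth) / n_neutral
        assert fp_rate < 0.05


class TestAssignCandidates:
    def _outliers(self, ids):
        table = pd.DataFrame({"locus_id": ids, "axis": "RDA1", "loading": 1.0, "z": 4.0})
        from seapop.gea import OutlierSet
        return OutlierSet(table, pd.DataFrame(), 3.0)

    def test_threshold_snp_assigned_to_its_variable(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame({"env1": rng.standard_normal(10),
                            "env2": np.linspace(-1, 1, 10)},
                           index=[f"S{i}" for i in range(10)])
        sites = [f"S{i}" for i in range(10) for _ in range(4)]
        d = np.zeros((40, 2), dtype=int)
        d[:, 0] = [2 if env.loc[s, "env2"] > 0 else 0 for s in sites]
        d[:, 1] = rng.integers(0, 3, 40)
        gm = make_gm(d, sites)
        res = assign_candidates(self._outliers(["L0"]), gm, env)
        assert res.loc[0, "variable"] == "env2"
        assert res.loc[0, "r"] > 0.8

    def test_tie_prefers_earlier_variable(self):
        v = np.linspace(-1, 1, 8)
        env = pd.DataFrame({"env1": v, "env2": v.copy()},
                           index=[f"S{i}" for i in range(8)])
        sites = [f"S{i}" for i in range(8)]
        d = np.array([[0], [0], [0], [1], [1], [2], [2], [2]])
        gm = make_gm(d, sites)
        res = assign_candidates(self._outliers(["L0"]), gm, env)
        assert res.loc[0, "variable"] == "env1"

    def test_zero_variance_snp_dropped(self):
        env = pd.DataFrame({"env1": np.arange(4.0)}, index=[f"S{i}" for i in range(4)])
        gm = make_gm(np.ones((4, 1), dtype=int), [f"S{i}" for i in range(4)])
        with pytest.warns(UserWarning):
            res = assign_candidates(self._outliers(["L0"]), gm, env)
        assert res.empty

    def test_truth_variables_recovered(self, adaptive_dataset):
        gm = adaptive_dataset.genotypes
        truth_ids = adaptive_dataset.truth["adaptive_locus_ids"]
        truth_var = dict(zip(truth_ids, adaptive_dataset.truth["adaptive_variable"]))
        res = assign_candidates(self._outliers(truth_ids), gm, adaptive_dataset.env)
        correct = (res["variable"] == res["locus_id"].map(truth_var)).mean()
        assert correct >= 0.8


class TestPolygenicScores:
    def _simple(self, k=4, n_sites=8, per=5, seed=0):
        rng = np.random.default_rng(seed)
        sites = [f"S{i}" for i in range(n_sites) for _ in range(per)]
        env = pd.DataFrame({"env1": np.linspace(-2, 2, n_sites)},
                           index=[f"S{i}" for i in range(n_sites)])
        d = rng.integers(0, 3, (n_sites * per, k))
        gm = make_gm(d, sites)
        assignment = pd.DataFrame({"locus_id": [f"L{j}" for j in range(k)],
                                   "variable": "env1"})
        return gm, assignment, env

    def test_homozygous_alt_scores_2k(self):
        gm, assignment, env = self._simple(k=5)
        d = gm.dosages.copy()
        d[:] = 2
        d[0, :] = 0  # keep loci polymorphic with positive orientation anchor
        gm2 = make_gm(d, gm.site_of_individual)
        pst = polygenic_scores(gm2, assignment, env)
        scores = pst.scores["env1"]
        assert set(scores.unique()) <= {0, 10}
        assert (scores.iloc[1:] == 10).all() or (scores.iloc[1:] == 0).all()

    def test_orientation_gives_nonnegative_slope(self):
        for seed in range(10):
            gm, assignment, env = self._simple(seed=seed)
            pst = polygenic_scores(gm, assignment, env)
            e = env.loc[[s for s in gm.site_of_individual], "env1"].to_numpy()
            slope = np.polyfit(e, pst.scores["env1"].to_numpy(), 1)[0]
            assert slope >= -1e-9

    def test_negated_variable_reflects_scores_same_fit(self):
        # negating the variable toggles every SNP orientation: scores map to
        # 2k - score, and the score~variable fit statistics are unchanged
        gm, assignment, env = self._simple(seed=3)
        pst1 = polygenic_scores(gm, assignment, env)
        pst2 = polygenic_scores(gm, assignment, -env)
        k = len(assignment)
        assert (pst2.scores["env1"] == 2 * k - pst1.scores["env1"]).all()
        assert pst1.fits.loc["env1", "adj_r2"] == pytest.approx(
            pst2.fits.loc["env1", "adj_r2"], abs=1e-9
        )

    def test_quadratic_relation_selected_by_aic(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            n_sites = 12
            sites = [f"S{i}" for i in range(n_sites) for _ in range(6)]
            e_site = np.linspace(0, 2, n_sites)
            env = pd.DataFrame({"env1": e_site}, index=[f"S{i}" for i in range(n_sites)])
            # allele frequency follows a convex quadratic cline: consistent
            # orientation across SNPs, curvature that a line cannot absorb
            p = np.clip(0.05 + 0.2 * e_site**2, 0, 0.9)
            d = np.column_stack([
                rng.binomial(2, p[[i // 6 for i in range(len(sites))]])
                for _ in range(12)
            ])
            gm = make_gm(d, sites)
            assignment = pd.DataFrame({"locus_id": [f"L{j}" for j in range(12)],
                                       "variable": "env1"})
            pst = polygenic_scores(gm, assignment, env)
            hits += pst.fits.loc["env1", "model"] == "quadratic"
        assert hits >= 9

    def test_missing_input_rejected(self):
        gm, assignment, env = self._simple()
        d = gm.dosages.copy()
        d[0, 0] = -1
        gm2 = make_gm(d, gm.site_of_individual)
        with pytest.raises(ValueError, match="impute"):
            polygenic_scores(gm2, assignment, env)
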