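"""Differentiation and diversity statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from seapop import synthgen
from seapop.geno_io import MISSING
from seapop.popstats import (
    amova,
    diversity,
    fst_groups,
    mantel_ibd,
    pairwise_fst,
    wc_components,
    weir_cockerham_theta,
)
from tests.conftest import make_gm


def wc_two_pop_oracle(n1, p1, h1, n2, p2, h2):
    """Scalar evaluation of the 1984 two-population component formulas."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestThetaEstimator:
    def test_single_locus_matches_hand_oracle(self):
        # pop1 genotypes [0,1,1,2]: n=4, p=0.5, h=0.5
        # pop2 genotypes [0,0,1,0]: n=4, p=0.125, h=0.25
        gm = make_gm(np.array([[0], [1], [1], [2], [0], [0], [1], [0]]),
                     ["P1"] * 4 + ["P2"] * 4)
        theta = weir_cockerham_theta(gm)
        a, b, c = wc_two_pop_oracle(4, 0.5, 0.5, 4, 1 / 8, 0.25)
        assert theta == pytest.approx(a / (a + b + c), abs=1e-12)
        assert theta == pytest.approx(1 / 6, abs=1e-12)  # frozen hand value

    def test_components_match_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 30, size=(2, 1)).astype(float)
            p = rng.uniform(0.05, 0.95, size=(2, 1))
            h = rng.uniform(0, 1, size=(2, 1))
            a, b, c = wc_components(n, p, h)
            ao, bo, co = wc_two_pop_oracle(n[0, 0], p[0, 0], h[0, 0], n[1, 0], p[1, 0], h[1, 0])
            assert np.allclose([a[0], b[0], c[0]], [ao, bo, co], atol=1e-12)

    def test_fixed_differences_give_theta_one(self):
        gm = make_gm(np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(int),
                     ["P1"] * 5 + ["P2"] * 5)
        assert weir_cockerham_theta(gm) == pytest.approx(1.0)

    def test_ratio_of_sums_between_per_set_values(self):
        rng = np.random.default_rng(7)
        gm = make_gm(rng.integers(0, 3, (40, 60)), ["P1"] * 20 + ["P2"] * 20)
        t_all = weir_cockerham_theta(gm)
        t1 = weir_cockerham_theta(gm.take_loci(np.arange(30)))
        t2 = weir_cockerham_theta(gm.take_loci(np.arange(30, 60)))
        assert min(t1, t2) - 1e-12 <= t_all <= max(t1, t2) + 1e-12


class TestPairwiseFst:
    def test_identical_frequencies_ci_covers_zero(self):
        cfg = synthgen.SimulationConfig(n_sites=2, n_per_site=100, n_clusters=1,
                                        n_neutral_loci=500, n_adaptive_loci=0,
                                        fst_between_clusters=0.0, fst_within_cluster=0.0,
                                        missing_rate=0.0, seed=3)
        gm = synthgen.simulate_seascape(cfg).genotypes
        fst = pairwise_fst(gm, n_boot=300, seed=1)
        pr = fst.pair("S01", "S02")
        assert abs(pr["theta"]) < 0.003
        assert pr["ci_low"] <= 0 <= pr["ci_high"]

    def test_point_estimates_deterministic_without_bootstrap(self):
        rng = np.random.default_rng(2)
        gm = make_gm(rng.integers(0, 3, (30, 40)), ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        f1 = pairwise_fst(gm, n_boot=0)
        f2 = pairwise_fst(gm, n_boot=0)
        assert f1.theta.equals(f2.theta)
        assert np.isnan(f1.p.to_numpy()[np.triu_indices(3, 1)]).all()

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        gm = make_gm(rng.integers(0, 3, (30, 50)), ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        fst = pairwise_fst(gm, n_boot=50, seed=0)
        t = fst.theta.to_numpy()
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 0)
        iu = np.triu_indices(3, 1)
        assert (fst.ci_low.to_numpy()[iu] <= fst.ci_high.to_numpy()[iu]).all()


class TestFstGroups:
    def _fake(self, sites, zero_pairs):
        n = len(sites)
        theta = pd.DataFrame(np.full((n, n), 0.01), index=sites, columns=sites)
        lo = pd.DataFrame(np.full((n, n), 0.005), index=sites, columns=sites)
        hi = pd.DataFrame(np.full((n, n), 0.02), index=sites, columns=sites)
        for a, b in zero_pairs:
            lo.loc[a, b] = lo.loc[b, a] = -0.001
        from seapop.popstats import FstMatrix
        nanp = pd.DataFrame(np.nan, index=sites, columns=sites)
        return FstMatrix(sites, theta, lo, hi, nanp, nanp, 0)

    def test_all_cis_exclude_zero_gives_singletons(self):
        g = fst_groups(self._fake(["A", "B", "C"], []))
        assert len(set(g.values())) == 3

    def test_single_zero_pair_merged(self):
        g = fst_groups(self._fake(["A", "B", "C", "D"], [("A", "B")]))
        assert g["A"] == g["B"]
        assert len(set(g.values())) == 3

    def test_chain_transitive_closure(self):
        g = fst_groups(self._fake(["A", "B", "C", "D"], [("A", "B"), ("B", "C")]))
        assert g["A"] == g["B"] == g["C"] != g["D"]


class TestDiversity:
    def test_all_heterozygotes_single_locus(self):
        gm = make_gm(np.ones((6, 1), dtype=int), ["S1"] * 6)
        t = diversity(gm, n_perm=50, seed=1).table
        assert t.loc["S1", "Ho"] == pytest.approx(1.0)
        assert t.loc["S1", "Fis"] < 0

    def test_fixed_site_counts_monomorphic(self):
        gm = make_gm(np.zeros((5, 3), dtype=int), ["S1"] * 5)
        t = diversity(gm, n_perm=0).table
        assert t.loc["S1", "Ho"] == 0 and t.loc["S1", "He"] == 0
        assert t.loc["S1", "n_monomorphic"] == 3 and t.loc["S1", "n_polymorphic"] == 0

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.binomial(2, 0.4, (40, 200)), ["S1"] * 40)
        t = diversity(gm, n_perm=100, seed=2).table
        assert t.loc["S1", "Fis_low"] <= t.loc["S1", "Fis"] <= t.loc["S1", "Fis_high"]

    def test_hw_site_interval_covers_zero_mostly(self):
        covered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gm = make_gm(rng.binomial(2, 0.5, (200, 500)), ["S1"] * 200)
            t = diversity(gm, n_perm=60, seed=seed).table
            if t.loc["S1", "Fis_low"] <= 0 <= t.loc["S1", "Fis_high"]:
                covered += 1
        assert covered >= 9

    def test_singleton_site_reported_as_nan(self):
        gm = make_gm(np.array([[0, 1], [1, 2], [0, 0]]), ["A", "A", "B"])
        t = diversity(gm, n_perm=0).table
        assert np.isnan(t.loc["B", "Ho"])


class TestAmova:
    def _grouping(self, sites, k=2):
        pop_of_site = {s: s for s in sites}
        group_of_pop = {s: f"G{i % k}" for i, s in enumerate(sites)}
        return pop_of_site, group_of_pop

    def test_identical_individuals_zero_components(self):
        # identical homozygotes: no allelic variation at any level
        gm = make_gm(np.full((12, 10), 2, dtype=int), [f"S{i // 3}" for i in range(12)])
        pos, gop = self._grouping(gm.sites)
        res = amova(gm, pos, gop, n_perm=10, seed=1)
        assert res.sigma_a == res.sigma_b == res.sigma_c == 0
        assert all(np.isnan(v) for v in res.pct)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, (24, 50)), [f"S{i // 6}" for i in range(24)])
        pos, gop = self._grouping(gm.sites)
        res = amova(gm, pos, gop, n_perm=20, seed=1)
        assert sum(res.pct) == pytest.approx(100, abs=1e-8)
        assert res.p_f_ct >= 1 / 21 and res.p_f_sc >= 1 / 21

    def test_two_group_structure_recovered(self):
        cfg = synthgen.SimulationConfig(
            n_sites=6, n_per_site=25, n_clusters=2, n_neutral_loci=800,
            n_adaptive_loci=0, fst_between_clusters=0.05, fst_within_cluster=0.0,
            missing_rate=0.0, seed=17,
        )
        d = synthgen.simulate_seascape(cfg)
        pos = {s: s for s in d.genotypes.sites}
        gop = {s: f"G{d.truth['cluster_of_site'][s]}" for s in d.genotypes.sites}
        res = amova(d.genotypes, pos, gop, n_perm=99, seed=1)
        assert res.f_ct == pytest.approx(0.05, abs=0.02)
        assert abs(res.f_sc) < 0.01

    def test_single_group_rejected(self):
        gm = make_gm(np.ones((8, 5), dtype=int), [f"S{i // 2}" for i in range(8)])
        with pytest.raises(ValueError):
            amova(gm, {s: s for s in gm.sites}, {s: "G0" for s in gm.sites}, n_perm=5)


class TestMantelIbd:
    def _fst_from_matrix(self, m, sites):
        from seapop.popstats import FstMatrix
        df = pd.DataFrame(m, index=sites, columns=sites)
        nanp = pd.DataFrame(np.nan, index=sites, columns=sites)
        return FstMatrix(sites, df, df, df, nanp, nanp, 0)

    def test_proportional_matrices_give_r_one_min_p(self):
        sites = [f"S{i}" for i in range(8)]
        pos = np.arange(8, dtype=float)
        d = np.abs(pos[:, None] - pos[None, :])
        fst = self._fst_from_matrix(0.001 * d, sites)
        res = mantel_ibd(fst, pd.DataFrame(d, index=sites, columns=sites),
                         n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_constant_matrix_returns_nan_with_warning(self):
        sites = list("ABCD")
        fst = self._fst_from_matrix(np.full((4, 4), 0.01) - 0.01 * np.eye(4), sites)
        d = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        with pytest.warns(UserWarning):
            res = mantel_ibd(fst, pd.DataFrame(d, index=sites, columns=sites), n_perm=99)
        assert np.isnan(res.r)

    def test_too_few_sites_rejected(self):
        sites = list("ABC")
        fst = self._fst_from_matrix(np.eye(3) * 0, sites)
        with pytest.raises(ValueError):
            mantel_ibd(fst, pd.DataFrame(np.ones((3, 3)), index=sites, columns=sites))

    def test_oracle_agreement_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(9)
        sites = [f"S{i}" for i in range(7)]
        a = rng.random((7, 7)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((7, 7)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        fst = self._fst_from_matrix(a, sites)
        res = mantel_ibd(fst, pd.DataFrame(b, index=sites, columns=sites), n_perm=99, seed=2)
        r_skbio, _, _ = skbio_mantel(SkbioDM(a), SkbioDM(b), permutations=0)
        assert res.r == pytest.approx(r_skbio, abs=1e-12)
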