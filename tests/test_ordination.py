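"""RDA core against brute-force and external oracles; screening and selection."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from seapop.ordination import (
    ordistep,
    rda_anova,
    rda_fit,
    screen_variables,
    varpart,
    vif,
)


def rda_oracle(y, x, z=None):
    """Explicit normal equations + eigen-decomposition of fitted values."""
    y = y - y.mean(axis=0)
    x = x - x.mean(axis=0)
    if z is not None:
        z = z - z.mean(axis=0)
        hz = z @ np.linalg.pinv(z.T @ z) @ z.T
        y = y - hz @ y
        x = x - hz @ x
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    yhat = h @ y
    vals = np.linalg.eigvalsh(yhat.T @ yhat)[::-1]
    vals = vals[vals > 1e-10 * max(vals.max(), 1.0)]
    r2 = np.trace(yhat.T @ yhat) / np.trace(y.T @ y)
    return yhat, vals, r2


class TestRdaFit:
    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(8, 21)
            m = rng.integers(2, 12)
            p = rng.integers(1, min(n - 3, 6))
            y = rng.standard_normal((n, m))
            x = rng.standard_normal((n, p))
            model = rda_fit(y, x)
            yhat, vals, r2 = rda_oracle(y, x)
            assert model.r2 == pytest.approx(r2, abs=1e-10)
            got = model.eigenvalues * (n - 1)
            assert np.allclose(np.sort(got)[::-1], vals[: len(got)], atol=1e-8)

    def test_partial_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = 15
            y = rng.standard_normal((n, 6))
            x = rng.standard_normal((n, 3))
            z = rng.standard_normal((n, 2))
            model = rda_fit(y, x, z)
            _, vals, r2 = rda_oracle(y, x, z)
            assert model.r2 == pytest.approx(r2, abs=1e-10)
            got = model.eigenvalues * (n - 1)
            assert np.allclose(got, vals[: len(got)], atol=1e-8)

    def test_y_equals_x_perfect_fit(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 1))
        model = rda_fit(x.copy(), x)
        assert model.r2 == pytest.approx(1.0)
        assert model.n_axes == 1

    def test_orthogonal_predictor_zero_r2(self):
        rng = np.random.default_rng(20)
        y = rng.standard_normal((10, 1))
        y -= y.mean()
        x = rng.standard_normal((10, 1))
        x -= x.mean()
        x -= ((x.T @ y).item() / (y.T @ y).item()) * y  # Gram–Schmidt against y
        model = rda_fit(y, x)
        assert model.r2 == pytest.approx(0.0, abs=1e-12)
        assert model.adj_r2 <= 0

    def test_adjusted_r2_below_r2(self):
        rng = np.random.default_rng(3)
        model = rda_fit(rng.standard_normal((12, 5)), rng.standard_normal((12, 2)))
        assert model.adj_r2 < model.r2

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="saturated"):
            rda_fit(rng.standard_normal((5, 3)), rng.standard_normal((5, 5)))

    def test_matches_vegan(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        y = rng.standard_normal((12, 7))
        x = rng.standard_normal((12, 3))
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{tmp_path}/y.csv", header=FALSE))
            X <- as.data.frame(read.csv("{tmp_path}/x.csv", header=FALSE))
            m <- rda(Y ~ ., data=X)
            adj <- RsquareAdj(m)
            cat(adj$r.squared, adj$adj.r.squared, eigenvals(m, model="constrained"), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        model = rda_fit(y, x)
        assert model.r2 == pytest.approx(vals[0], abs=1e-6)
        assert model.adj_r2 == pytest.approx(vals[1], abs=1e-6)
        assert np.allclose(model.eigenvalues, vals[2:], atol=1e-6)


class TestRdaAnova:
    def test_perfect_relation_minimal_p(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 2))
        y = x @ rng.standard_normal((2, 4))
        model = rda_fit(y, x)
        res = rda_anova(model, "global", n_perm=99, seed=1)
        assert res.table["p"].iloc[0] == pytest.approx(1 / 100)

    def test_duplicated_predictor_margin_p_high(self):
        rng = np.random.default_rng(6)
        x1 = rng.standard_normal(25)
        y = np.outer(x1, rng.standard_normal(3)) + 0.1 * rng.standard_normal((25, 3))
        x = np.column_stack([x1, x1])
        model = rda_fit(y, x)
        res = rda_anova(model, "margin", n_perm=99, seed=1)
        # a duplicated column has zero unique contribution (rank-0 residual)
        assert (res.table["p"] == 1.0).all()

    def test_axis_test_flags_only_real_axes(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 3))
        y = np.column_stack([x[:, 0] * 2, x[:, 0], rng.standard_normal(30)])
        y = y + 0.05 * rng.standard_normal(y.shape)
        model = rda_fit(y, x)
        res = rda_anova(model, "axis", n_perm=99, seed=1)
        assert res.table["p"].iloc[0] < 0.05
        assert res.table["p"].iloc[-1] > 0.05

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((15, 4))
        x = rng.standard_normal((15, 2))
        model = rda_fit(y, x)
        p1 = rda_anova(model, "global", n_perm=49, seed=3).table["p"].iloc[0]
        p2 = rda_anova(model, "global", n_perm=49, seed=3).table["p"].iloc[0]
        assert p1 == p2


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        assert np.allclose(vif(x).to_numpy(), 1.0)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(9)
        c = rng.standard_normal(20)
        v = vif(np.column_stack([c, c, rng.standard_normal(20)]))
        assert np.isinf(v.iloc[0]) and np.isinf(v.iloc[1])

    def test_closed_form_on_correlated_gaussians(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(5000)
        x = np.column_stack([
            z + 0.3 * rng.standard_normal(5000),
            z + 0.3 * rng.standard_normal(5000),
            rng.standard_normal(5000),
        ])
        v = vif(x)
        # oracle: R² of column 0 on the others via direct regression
        x0 = x[:, 0] - x[:, 0].mean()
        xo = x[:, 1:] - x[:, 1:].mean(axis=0)
        beta, *_ = np.linalg.lstsq(xo, x0, rcond=None)
        r2 = 1 - ((x0 - xo @ beta) ** 2).sum() / (x0**2).sum()
        assert v.iloc[0] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestScreening:
    def test_duplicate_variable_pruned(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal((12, 5))
        v = rng.standard_normal(12)
        env = pd.DataFrame({"a": v, "b": v.copy(), "c": rng.standard_normal(12)})
        kept = screen_variables(y, env, p_thresh=1.0, n_perm=49, seed=1)
        assert not ({"a", "b"} <= set(kept))

    def test_independent_variable_usually_dropped(self):
        rng = np.random.default_rng(12)
        dropped = 0
        for seed in range(20):
            y = rng.standard_normal((12, 5))
            env = pd.DataFrame({"noise": rng.standard_normal(12)})
            kept = screen_variables(y, env, p_thresh=0.1, n_perm=99, seed=seed)
            dropped += "noise" not in kept
        assert dropped >= 14  # ~1-p_thresh of the time

    def test_structured_roster_shrinks(self):
        # 8 highly inter-correlated "temperature" + 3 "salinity" + 3 "turbidity"
        rng = np.random.default_rng(13)
        n = 13
        t = rng.standard_normal(n)
        s = rng.standard_normal(n)
        u = rng.standard_normal(n)
        cols = {f"temp{i}": t + 0.3 * rng.standard_normal(n) for i in range(8)}
        cols |= {f"sal{i}": s + 0.3 * rng.standard_normal(n) for i in range(3)}
        cols |= {f"turb{i}": u + 0.3 * rng.standard_normal(n) for i in range(3)}
        env = pd.DataFrame(cols)
        y = np.column_stack([t, s]) @ rng.standard_normal((2, 6)) + 0.3 * rng.standard_normal((n, 6))
        kept = screen_variables(y, env, p_thresh=0.5, n_perm=99, seed=1)
        assert 0 < len(kept) < 14
        # at most a couple of survivors per correlated family
        for fam in ("temp", "sal", "turb"):
            assert sum(k.startswith(fam) for k in kept) <= 3


class TestOrdistep:
    def test_single_true_predictor_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x_true = rng.standard_normal(20)
            noise = rng.standard_normal((20, 3))
            y = np.outer(x_true, rng.standard_normal(4)) + 0.3 * rng.standard_normal((20, 4))
            X = pd.DataFrame(np.column_stack([x_true, noise]),
                             columns=["true", "n1", "n2", "n3"])
            sel = ordistep(y, X, n_perm=99, seed=seed)
            hits += sel == ["true"]
        assert hits >= 9

    def test_all_noise_often_empty(self):
        empties = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            y = rng.standard_normal((15, 4))
            X = pd.DataFrame(rng.standard_normal((15, 3)), columns=list("abc"))
            sel = ordistep(y, X, n_perm=99, seed=seed)
            empties += len(sel) == 0
        assert empties >= 6

    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(14)
        x_true = rng.standard_normal(15)
        y = np.outer(x_true, np.ones(3))
        X = pd.DataFrame(np.column_stack([rng.standard_normal(15), x_true]),
                         columns=["noise", "perfect"])
        sel = ordistep(y, X, n_perm=99, seed=1)
        assert sel[0] == "perfect"


class TestVarpart:
    def test_fractions_close_exactly(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal((20, 6))
        e = rng.standard_normal((20, 2))
        s = rng.standard_normal((20, 2))
        vp = varpart(y, e, s, n_perm=49, seed=1)
        total = vp.env_unique + vp.joint + vp.spa_unique + vp.residual
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_spatial_set_contributes_nothing(self):
        rng = np.random.default_rng(16)
        n = 40
        e = rng.standard_normal((n, 2))
        y = e @ rng.standard_normal((2, 5)) + 0.2 * rng.standard_normal((n, 5))
        s = rng.standard_normal((n, 2))
        vp = varpart(y, e, s, n_perm=49, seed=1)
        assert vp.env_unique == pytest.approx(rda_fit(y, e).adj_r2, abs=0.1)
        assert abs(vp.spa_unique) < 0.05

    def test_spatially_structured_env_yields_joint_fraction(self):
        rng = np.random.default_rng(17)
        n = 30
        grad = np.linspace(-1, 1, n)
        env = grad + 0.2 * rng.standard_normal(n)
        spa = np.column_stack([grad, grad**2])
        y = np.outer(env, rng.standard_normal(5)) + 0.2 * rng.standard_normal((n, 5))
        vp = varpart(y, env[:, None], spa, n_perm=49, seed=1)
        assert vp.joint > 0.1
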