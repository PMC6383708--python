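"""Constrained ordination (RDA) with permutation tests and model selection.

Redundancy analysis regresses a multivariate response (site allele
frequencies, or individual dosages) on predictor variables by least
squares and eigen-decomposes the fitted values; the canonical axes are the
directions of response variation explained by the predictors. Partial RDA
residualizes response and predictors on a conditioning matrix first,
isolating the unique contribution of a predictor set.

This module also provides pseudo-F permutation ANOVA (global, marginal
per-term, sequential per-axis), variance-inflation factors, the
correlation/significance/VIF screening chain for candidate environmental
variables, forward-backward stepwise selection, and adjusted-R² variance
partitioning between environmental and spatial predictor sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    if isinstance(x, pd.Series):
        return x.to_numpy(dtype=float)[:, None], [str(x.name or "x1")]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _project_out(a: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    """Residuals of (centered) a after regression on (centered) z."""
    if z is None or z.shape[1] == 0:
        return a
    beta, *_ = np.linalg.lstsq(z, a, rcond=None)
    return a - z @ beta


@dataclass
class RdaModel:
    """A fitted (partial) redundancy analysis.

    ``eigenvalues`` are per-axis constrained variances (sum-of-squares of
    fitted values along each canonical axis divided by n−1); ``row_scores``
    are fitted ("linear-combination") site/individual scores; ``loadings``
    are Pearson correlations of each response column with each axis;
    ``biplot_scores`` likewise for predictors.
    """

    eigenvalues: np.ndarray
    row_scores: np.ndarray
    loadings: pd.DataFrame  # response columns × axes
    biplot_scores: pd.DataFrame  # predictors × axes
    r2: float
    adj_r2: float
    rank_x: int
    n: int
    predictor_names: list[str] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)
    # stored matrices for permutation tests (residualized where conditioned)
    _y: np.ndarray | None = None
    _x: np.ndarray | None = None
    _z: np.ndarray | None = None
    _rank_z: int = 0

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def rda_fit(Y, X, Z=None, scale: bool = False) -> RdaModel:
    """Fit a (partial) RDA of response Y on predictors X, conditioning on Z.

    Columns of Y are centred (optionally scaled to unit variance); with Z
    given, Y and X are residualized on Z. Fitted values Ŷ = X(XᵀX)⁻XᵀY are
    obtained by a rank-revealing least-squares solve; canonical axes are
    the principal axes of Ŷ. R² = tr(ŶᵀŶ)/tr(YᵀY) on the (residualized)
    matrices; adjusted R² uses Ezekiel's formula with rank-based degrees of
    freedom.
    """
    y, ynames = _as_matrix(Y)
    x, xnames = _as_matrix(X)
    if y.shape[0] != x.shape[0]:
        raise ValueError("Y and X row counts differ")
    n = y.shape[0]
    y = _center(y)
    if scale:
        sd = y.std(axis=0, ddof=1)
        y = y / np.where(sd > 0, sd, 1.0)
    x = _center(x)
    z = None
    rank_z = 0
    if Z is not None:
        z, _ = _as_matrix(Z)
        z = _center(z)
        rank_z = np.linalg.matrix_rank(z)
        y = _project_out(y, z)
        x = _project_out(x, z)
    rank_x = np.linalg.matrix_rank(x) if x.size else 0
    if n <= rank_x + rank_z + 1:
        raise ValueError("saturated model: n must exceed rank(X) + rank(Z) + 1")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    tol = max(yhat.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    keep = s > max(tol, 1e-12)
    u, s = u[:, keep], s[keep]
    row_scores = u * s
    ss_tot = (y**2).sum()
    ss_fit = (s**2).sum()
    r2 = float(ss_fit / ss_tot) if ss_tot > 0 else 0.0
    denom = n - rank_z - rank_x - 1
    adj_r2 = 1 - (1 - r2) * (n - rank_z - 1) / denom if denom > 0 else np.nan
    loadings = _corr_with_axes(y, row_scores)
    biplot = _corr_with_axes(x, row_scores)
    axes = [f"RDA{k + 1}" for k in range(row_scores.shape[1])]
    return RdaModel(
        eigenvalues=s**2 / max(n - 1, 1),
        row_scores=row_scores,
        loadings=pd.DataFrame(loadings, index=ynames, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=xnames, columns=axes),
        r2=r2,
        adj_r2=float(adj_r2),
        rank_x=int(rank_x),
        n=n,
        predictor_names=xnames,
        response_names=ynames,
        _y=y,
        _x=x,
        _z=z,
        _rank_z=int(rank_z),
    )


def _corr_with_axes(cols: np.ndarray, scores: np.ndarray) -> np.ndarray:
    if scores.shape[1] == 0:
        return np.zeros((cols.shape[1], 0))
    c = _center(cols)
    s = _center(scores)
    denom = np.sqrt((c**2).sum(axis=0))[:, None] * np.sqrt((s**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (c.T @ s) / denom
    return np.nan_to_num(out)


# ---------------------------------------------------------------------------
# permutation ANOVA


@dataclass
class AnovaResult:
    table: pd.DataFrame  # term, F, p, df
    n_perm: int
    seed: int | None

    def p_of(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _f_global(y: np.ndarray, x: np.ndarray, rank_x: int, rank_z: int) -> float:
    n = y.shape[0]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    ss_fit = (yhat**2).sum()
    ss_res = ((y - yhat) ** 2).sum()
    df_res = n - rank_x - rank_z - 1
    if ss_res <= 0 or df_res <= 0:
        return np.inf
    return (ss_fit / rank_x) / (ss_res / df_res)


def rda_anova(
    model: RdaModel, by: str = "global", n_perm: int = 1000, seed: int | None = None
) -> AnovaResult:
    """Permutation pseudo-F tests of a fitted RDA.

    ``by="global"`` tests the whole constrained fraction; ``"margin"``
    tests each predictor with all others retained (conditioned out);
    ``"axis"`` tests each canonical axis sequentially, conditioning on the
    preceding axes. Rows of the (reduced-model residualized) response are
    permuted; p = (1 + #{F* ≥ F}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if model._y is None:
        raise ValueError("model does not carry stored matrices")
    rng = np.random.default_rng(seed)
    y, x = model._y, model._x
    n = model.n
    rows = []
    if by == "global":
        f_obs = _f_global(y, x, model.rank_x, model._rank_z)
        hits = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            if _f_global(yp, x, model.rank_x, model._rank_z) >= f_obs:
                hits += 1
        rows.append(("global", f_obs, (1 + hits) / (n_perm + 1), model.rank_x))
    elif by == "margin":
        for j, name in enumerate(model.predictor_names):
            xj = x[:, [j]]
            xo = np.delete(x, j, axis=1)
            f_obs, p = _partial_term_test(y, xj, xo, model._rank_z, n_perm, rng)
            rows.append((name, f_obs, p, 1))
    elif by == "axis":
        df_res = n - model._rank_z - model.rank_x - 1
        ss_res = ((y - _x_fit(x, y)) ** 2).sum()
        for k in range(model.n_axes):
            # condition on the preceding canonical axes
            prev = model.row_scores[:, :k]
            yk = _project_out(y, prev) if k else y
            xk = _project_out(x, prev) if k else x
            lam = _first_eig_ss(xk, yk)
            f_obs = lam / (ss_res / df_res) if ss_res > 0 and df_res > 0 else np.inf
            hits = 0
            for _ in range(n_perm):
                yp = yk[rng.permutation(n)]
                lam_p = _first_eig_ss(xk, yp)
                ss_res_p = ((yp - _x_fit(x, yp)) ** 2).sum()
                f_p = lam_p / (ss_res_p / df_res) if ss_res_p > 0 else np.inf
                if f_p >= f_obs:
                    hits += 1
            rows.append((f"RDA{k + 1}", f_obs, (1 + hits) / (n_perm + 1), 1))
    else:
        raise ValueError(f"unknown test scope: {by!r}")
    return AnovaResult(pd.DataFrame(rows, columns=["term", "F", "p", "df"]), n_perm, seed)


def _x_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return x @ beta


def _first_eig_ss(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of squares along the first canonical axis of the fit of y on x."""
    s = np.linalg.svd(_x_fit(x, y), compute_uv=False)
    return float(s[0] ** 2) if len(s) else 0.0


def _partial_term_test(
    y: np.ndarray,
    x_term: np.ndarray,
    x_cond: np.ndarray,
    rank_z0: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Pseudo-F and permutation p of one term given conditioning columns."""
    n = y.shape[0]
    yr = _project_out(y, x_cond) if x_cond.size else y
    xr = _project_out(x_term, x_cond) if x_cond.size else x_term
    # rank of the term's unique part, judged against the term's own scale so a
    # duplicated column (residual = numerical noise) counts as rank 0
    sv = np.linalg.svd(xr, compute_uv=False) if xr.size else np.array([])
    scale = np.linalg.norm(x_term) if x_term.size else 1.0
    rank_t = int((sv > 1e-8 * max(scale, 1e-300)).sum())
    rank_c = np.linalg.matrix_rank(x_cond) if x_cond.size else 0
    df_res = n - rank_z0 - rank_c - rank_t - 1
    if rank_t == 0 or df_res <= 0:
        return 0.0, 1.0
    yhat = _x_fit(xr, yr)
    ss_fit = (yhat**2).sum()
    ss_res = ((yr - yhat) ** 2).sum()
    if ss_res <= 0:
        return np.inf, 1.0 / (n_perm + 1)
    f_obs = (ss_fit / rank_t) / (ss_res / df_res)
    hits = 0
    for _ in range(n_perm):
        yp = yr[rng.permutation(n)]
        yhat_p = _x_fit(xr, yp)
        ss_fit_p = (yhat_p**2).sum()
        ss_res_p = ((yp - yhat_p) ** 2).sum()
        if ss_res_p <= 0:
            hits += 1
            continue
        if (ss_fit_p / rank_t) / (ss_res_p / df_res) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# VIF and screening


def vif(X) -> pd.Series:
    """Variance inflation factor per column: 1/(1−R²_j) regressing j on the rest."""
    x, names = _as_matrix(X)
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    x = _center(x)
    out = {}
    for j, name in enumerate(names):
        xj = x[:, j]
        xo = np.delete(x, j, axis=1)
        ss_tot = (xj**2).sum()
        if ss_tot == 0:
            out[name] = np.nan
            continue
        res = xj - _x_fit(xo, xj[:, None])[:, 0]
        r2 = 1 - (res**2).sum() / ss_tot
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def screen_variables(
    Y,
    candidates: pd.DataFrame,
    p_thresh: float = 0.1,
    corr_prune: float = 0.7,
    vif_max: float = 10.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[str]:
    """Three-step environmental-variable screen before stepwise selection.

    1. Greedy correlation pruning: while any pair has |Pearson r| ≥
       ``corr_prune``, take the strongest such pair and drop the member with
       the higher mean |r| to all remaining variables (tie: later column).
    2. Single-variable RDA permutation ANOVA; keep p ≤ ``p_thresh``.
    3. Iterative VIF filter at ``vif_max``.
    """
    x, names = _as_matrix(candidates)
    keep = list(range(x.shape[1]))
    # step 1: correlation pruning
    while len(keep) > 1:
        sub = x[:, keep]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        r = np.nan_to_num(r)
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        if absr.max() < corr_prune:
            break
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        mean_i = absr[i].mean()
        mean_j = absr[j].mean()
        drop_local = max(i, j) if np.isclose(mean_i, mean_j) else (i if mean_i > mean_j else j)
        keep.pop(drop_local)
    # step 2: per-variable significance
    rng = np.random.default_rng(seed)
    survivors = []
    for k in keep:
        m = rda_fit(Y, x[:, [k]])
        res = rda_anova(m, by="global", n_perm=n_perm, seed=int(rng.integers(2**31)))
        if res.table["p"].iloc[0] <= p_thresh:
            survivors.append(k)
    if not survivors:
        warnings.warn("no variable passed the significance screen")
        return []
    # step 3: VIF
    while len(survivors) > 1:
        v = vif(pd.DataFrame(x[:, survivors], columns=[names[k] for k in survivors]))
        if v.max() < vif_max:
            break
        survivors.pop(int(np.argmax(v.to_numpy())))
    return [names[k] for k in survivors]


# ---------------------------------------------------------------------------
# stepwise selection


def ordistep(
    Y,
    X_full: pd.DataFrame,
    p_in: float = 0.05,
    p_out: float = 0.1,
    n_perm: int = 199,
    seed: int | None = None,
    max_steps: int = 50,
) -> list[str]:
    """Forward-backward stepwise selection by marginal permutation tests.

    At each step the best candidate term (lowest permutation p, then
    highest F) is added if p ≤ ``p_in``; then any included term whose
    marginal p (others retained) exceeds ``p_out`` is dropped. Stops when
    nothing changes or after ``max_steps``. Deterministic given ``seed``.
    """
    x, names = _as_matrix(X_full)
    y, _ = _as_matrix(Y)
    y = _center(y)
    x = _center(x)
    rng = np.random.default_rng(seed)
    included: list[int] = []
    for _ in range(max_steps):
        changed = False
        # forward
        candidates = [j for j in range(x.shape[1]) if j not in included]
        best = None
        for j in candidates:
            f, p = _partial_term_test(
                y, x[:, [j]], x[:, included], 0, n_perm, np.random.default_rng(int(rng.integers(2**31)))
            )
            if p <= p_in and (best is None or (p, -f) < (best[1], -best[2])):
                best = (j, p, f)
        if best is not None:
            included.append(best[0])
            changed = True
        # backward
        if len(included) > 1 or (included and not changed):
            worst = None
            for j in included:
                others = [k for k in included if k != j]
                f, p = _partial_term_test(
                    y, x[:, [j]], x[:, others], 0, n_perm, np.random.default_rng(int(rng.integers(2**31)))
                )
                if p > p_out and (worst is None or p > worst[1]):
                    worst = (j, p)
            if worst is not None:
                included.remove(worst[0])
                changed = True
        if not changed:
            break
    return [names[j] for j in included]


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass
class VarpartResult:
    """Adjusted-R² fractions: env-unique [a], joint [b], spatial-unique [c]."""

    env_unique: float
    joint: float
    spa_unique: float
    residual: float
    p_env_unique: float
    p_spa_unique: float
    p_global: float


def varpart(Y, X_env, X_spa, n_perm: int = 999, seed: int | None = None) -> VarpartResult:
    """Partition response variance between two predictor sets.

    Fractions are differences of Ezekiel-adjusted R²: [a] = adjR²(both) −
    adjR²(spa), [c] = adjR²(both) − adjR²(env), [b] by closure; residual =
    1 − adjR²(both), so the four fractions sum to 1 exactly. The unique
    fractions are tested by permutation ANOVA on the conditioned models,
    the total by the global test of the combined model.
    """
    xe, enames = _as_matrix(X_env)
    xs, snames = _as_matrix(X_spa)
    if xe.shape[1] == 0 or xs.shape[1] == 0:
        raise ValueError("both predictor sets must be non-empty")
    shared = set(map(tuple, xe.T)) & set(map(tuple, xs.T))
    if shared:
        warnings.warn("identical columns appear in both predictor sets")
    rng = np.random.default_rng(seed)
    both = np.column_stack([xe, xs])
    adj_ab = rda_fit(Y, both).adj_r2
    adj_e = rda_fit(Y, xe).adj_r2
    adj_s = rda_fit(Y, xs).adj_r2
    a = adj_ab - adj_s
    c = adj_ab - adj_e
    b = adj_e + adj_s - adj_ab
    resid = 1 - adj_ab
    m_a = rda_fit(Y, xe, Z=xs)
    m_c = rda_fit(Y, xs, Z=xe)
    m_g = rda_fit(Y, both)
    p_a = rda_anova(m_a, "global", n_perm, int(rng.integers(2**31))).table["p"].iloc[0]
    p_c = rda_anova(m_c, "global", n_perm, int(rng.integers(2**31))).table["p"].iloc[0]
    p_g = rda_anova(m_g, "global", n_perm, int(rng.integers(2**31))).table["p"].iloc[0]
    return VarpartResult(float(a), float(b), float(c), float(resid), float(p_a), float(p_c), float(p_g))
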