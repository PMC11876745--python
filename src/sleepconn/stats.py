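"""Edgewise mixed-effects comparison of sleep-state connectomes.

Each connectome edge (Fisher-z correlation) is modeled with a linear
mixed-effects model: sleep state (AS = 1, QS = 0) is the fixed effect of
interest, participant is a random intercept, and postmenstrual age, sex and
mean head motion can be added as covariates.  Per-edge p-values are
corrected with the Benjamini-Yekutieli (BY) step-up procedure (valid under
arbitrary dependence between edges), and t statistics are converted to
Cohen's D effect sizes via ``D = 2 t / sqrt(df)``.

The random-intercept model is fit by restricted maximum likelihood with a
solver specialized to a single grouping factor.  For the covariance
``V(theta) = I + theta Z Z^T`` (theta = participant variance over residual
variance) the inverse and determinant are closed-form per participant
block, so the REML criterion profile in theta is cheap to evaluate and —
crucially — can be evaluated for thousands of edges at once as batched
linear algebra.  A coarse log-grid search followed by golden-section
refinement locates each edge's theta; a boundary solution theta = 0 (zero
participant variance) degenerates exactly to OLS, which is reported as a
fallback with ordinary residual degrees of freedom.  Degrees of freedom for
mixed fits use the between-within rule
``df = n_obs - n_participants - n_fixed`` (fixed effects counted without
the intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EdgeStats",
    "fit_edge_lme",
    "edgewise_analysis",
    "by_fdr",
    "t_to_cohens_d",
    "effect_size_summary",
    "power_analysis",
    "calibrate_delta_z",
]

ADJUST_COLUMNS = ("pma_weeks", "sex", "mean_fd")
#: theta = sigma_participant^2 / sigma_residual^2 search grid (log-spaced)
_THETA_GRID = np.concatenate([[0.0], np.logspace(-6, 4, 51)])
_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# REML machinery for y = X beta + Z u + e with a single grouping factor
# ---------------------------------------------------------------------------

@dataclass
class _Precomp:
    X: np.ndarray          # (n, p)
    Y: np.ndarray          # (n, m)
    groups: np.ndarray     # (n,) integer codes
    Xg: np.ndarray         # (g, p) group sums of X
    Yg: np.ndarray         # (g, m) group sums of Y
    XtX: np.ndarray        # (p, p)
    XtY: np.ndarray        # (p, m)
    yty: np.ndarray        # (m,)
    sizes: np.ndarray      # (g,)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def g(self) -> int:
        return self.sizes.size


def _precompute(X: np.ndarray, Y: np.ndarray, groups: np.ndarray) -> _Precomp:
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    Xg = np.zeros((g, X.shape[1]))
    Yg = np.zeros((g, Y.shape[1]))
    np.add.at(Xg, codes, X)
    np.add.at(Yg, codes, Y)
    sizes = np.bincount(codes).astype(float)
    return _Precomp(X, Y, codes, Xg, Yg, X.T @ X, X.T @ Y,
                    np.einsum("nm,nm->m", Y, Y), sizes)


def _reml_pieces(pc: _Precomp, theta: np.ndarray):
    """Batched REML quantities at per-edge theta.

    Returns (criterion, beta, XtVX_inv, ssr) where criterion is the
    -2 profile REML log-likelihood up to an additive constant and
    ssr = y' P y (the weighted residual sum of squares).
    """
    theta = np.asarray(theta, dtype=float)
    m = pc.Y.shape[1]
    # c_{i,j} = theta_j / (1 + theta_j * n_i)   (g, m)
    c = theta[None, :] / (1.0 + theta[None, :] * pc.sizes[:, None])
    XtVX = pc.XtX[None, :, :] - np.einsum("gm,gp,gq->mpq", c, pc.Xg, pc.Xg)
    XtVy = pc.XtY - pc.Xg.T @ (c * pc.Yg)                       # (p, m)
    ytVy = pc.yty - np.einsum("gm,gm->m", c, pc.Yg ** 2)        # (m,)
    beta = np.linalg.solve(XtVX, XtVy.T[:, :, None])[:, :, 0]   # (m, p)
    ssr = np.maximum(ytVy - np.einsum("pm,mp->m", XtVy, beta), 1e-300)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    logdet_v = np.log1p(np.outer(pc.sizes, theta)).sum(axis=0)  # (m,)
    crit = (pc.n - pc.p) * np.log(ssr) + logdet_v + logdet_xvx
    XtVX_inv = np.linalg.inv(XtVX)
    return crit, beta, XtVX_inv, ssr


def _crit_only(pc: _Precomp, theta: np.ndarray) -> np.ndarray:
    crit, *_ = _reml_pieces(pc, theta)
    return crit


def _profile_theta(pc: _Precomp, n_golden: int = 35) -> np.ndarray:
    """Per-edge REML variance ratio via grid search + golden-section.

    The grid stage evaluates the profiled criterion for every edge at every
    grid theta; edges whose minimum lies in the grid interior are then
    refined by a vectorized golden-section search in log theta over the
    bracketing grid cell.
    """
    m = pc.Y.shape[1]
    crits = np.empty((_THETA_GRID.size, m))
    for k, th in enumerate(_THETA_GRID):
        crits[k] = _crit_only(pc, np.full(m, th))
    best = crits.argmin(axis=0)
    theta = _THETA_GRID[best]
    interior = (best > 0) & (best < _THETA_GRID.size - 1)
    if not interior.any():
        return theta
    a = np.log(_THETA_GRID[np.maximum(best - 1, 1)])
    b = np.log(_THETA_GRID[np.minimum(best + 1, _THETA_GRID.size - 1)])
    x1 = b - _GOLD * (b - a)
    x2 = a + _GOLD * (b - a)

    def crit_at(logx: np.ndarray) -> np.ndarray:
        return _crit_only(pc, np.where(interior, np.exp(logx), theta))

    f1 = crit_at(x1)
    f2 = crit_at(x2)
    for _ in range(n_golden):
        move_right = f1 >= f2  # minimum is in [x1, b]
        new_a = np.where(move_right, x1, a)
        new_b = np.where(move_right, b, x2)
        new_x1 = np.where(move_right, x2, new_b - _GOLD * (new_b - new_a))
        new_x2 = np.where(move_right, new_a + _GOLD * (new_b - new_a), x1)
        eval_pt = np.where(move_right, new_x2, new_x1)
        f_eval = crit_at(eval_pt)
        new_f1 = np.where(move_right, f2, f_eval)
        new_f2 = np.where(move_right, f_eval, f1)
        a, b, x1, x2, f1, f2 = new_a, new_b, new_x1, new_x2, new_f1, new_f2
    refined = np.exp((a + b) / 2.0)
    crit_ref = crit_at(np.log(refined))
    take = interior & (crit_ref <= crits[best, np.arange(m)])
    return np.where(take, refined, theta)


def _design_matrix(design: pd.DataFrame, adjust: bool) -> tuple[np.ndarray, list[str]]:
    cols = ["state"] + ([c for c in ADJUST_COLUMNS] if adjust else [])
    missing = [c for c in cols + ["participant"] if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {', '.join(missing)}")
    X = np.column_stack([np.ones(len(design))] + [design[c].to_numpy(float) for c in cols])
    return X, ["intercept"] + cols


def _fit_many(Y: np.ndarray, design: pd.DataFrame, adjust: bool):
    """Fit the random-intercept model to every column of Y.

    Returns a dict of per-edge arrays: beta (state coefficient), se, t, df,
    p and an ols_fallback flag.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X, names = _design_matrix(design, adjust)
    n, p = X.shape
    states = design["state"].to_numpy(float)
    if len(np.unique(states)) < 2:
        raise ValueError("design has runs in only one sleep state")
    if design["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    if n != Y.shape[0]:
        raise ValueError("edge data and design have different numbers of runs")
    if n - p < 1:
        raise ValueError("too few runs for the fixed-effect design")
    pc = _precompute(X, Y, design["participant"].to_numpy())

    # the random intercept is unusable when every participant contributes a
    # single run, or when the between-within rule leaves no residual df
    if (pc.sizes == 1).all() or n - pc.g - (p - 1) < 1:
        theta = np.zeros(Y.shape[1])
    else:
        theta = _profile_theta(pc)
    _, beta_all, XtVX_inv, ssr = _reml_pieces(pc, theta)
    fallback = theta == 0.0
    df = np.where(fallback, n - p, n - pc.g - (p - 1)).astype(float)
    sigma2 = ssr / (n - p)
    k = names.index("state")
    se = np.sqrt(sigma2 * XtVX_inv[:, k, k])
    beta = beta_all[:, k]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
        pvals = 2.0 * _stats.t.sf(np.abs(t), np.maximum(df, 1e-9))
    return {"beta": beta, "se": se, "t": t, "df": df, "p": pvals,
            "ols_fallback": fallback}


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit_edge_lme(edge_values: np.ndarray, design: pd.DataFrame,
                 adjust: bool = False) -> tuple[float, float, float, float, float]:
    """Random-intercept LME for one edge: (beta, se, t, df, p) for state.

    When the random intercept is inestimable or its REML estimate hits the
    zero boundary, the fit degenerates to OLS (with residual df) — common
    at small sample sizes and reported via `edgewise_analysis`'s
    ols_fallback column.
    """
    res = _fit_many(np.asarray(edge_values, float)[:, None], design, adjust)
    return tuple(float(res[k][0]) for k in ("beta", "se", "t", "df", "p"))


@dataclass(frozen=True)
class EdgeStats:
    """Edgewise result table plus its effect-size summary."""

    table: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return len(self.table)

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_by"] < q]


def edgewise_analysis(Z: np.ndarray, design: pd.DataFrame, adjust: bool = False,
                      edge_index: tuple[np.ndarray, np.ndarray] | None = None) -> EdgeStats:
    """Fit the state model to every edge and append BY-q and Cohen's D.

    Z is (n_runs, n_edges) of Fisher-z values aligned with the design rows;
    `edge_index` optionally supplies the (i, j) node pairs for the table.
    """
    Z = np.asarray(Z, dtype=float)
    res = _fit_many(Z, design, adjust)
    table = pd.DataFrame(res)
    table.insert(0, "edge", np.arange(Z.shape[1]))
    if edge_index is not None:
        table.insert(1, "node_i", edge_index[0])
        table.insert(2, "node_j", edge_index[1])
    table["q_by"] = by_fdr(table["p"].to_numpy())
    table["cohens_d"] = t_to_cohens_d(table["t"].to_numpy(), table["df"].to_numpy())
    return EdgeStats(table)


def by_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values.

    The BY penalty c(m) = sum_{i=1..m} 1/i makes the procedure valid under
    arbitrary dependence; q-values are capped at 1 and dominate
    Benjamini-Hochberg q-values elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def t_to_cohens_d(t: np.ndarray | float, df: np.ndarray | float):
    """Cohen's D from a t statistic: ``D = 2 t / sqrt(df)``.

    The two-group conversion used for mixed-model contrasts; the sign of D
    follows the sign of t.
    """
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr <= 0):
        raise ValueError("df must be positive")
    d = 2.0 * np.asarray(t, dtype=float) / np.sqrt(df_arr)
    return float(d) if np.isscalar(t) and np.isscalar(df) else d


@dataclass(frozen=True)
class EffectSizeSummary:
    """Binned |D| fractions (negligible/small/medium/large) and
    direction-conditional mean |D|."""

    frac_negligible: float  # |D| < 0.2
    frac_small: float       # 0.2 <= |D| < 0.5
    frac_medium: float      # 0.5 <= |D| < 0.8
    frac_large: float       # |D| >= 0.8
    mean_abs_d_as_greater: float
    mean_abs_d_qs_greater: float

    def to_dict(self) -> dict:
        return {
            "frac_negligible": self.frac_negligible, "frac_small": self.frac_small,
            "frac_medium": self.frac_medium, "frac_large": self.frac_large,
            "mean_abs_d_as_greater": self.mean_abs_d_as_greater,
            "mean_abs_d_qs_greater": self.mean_abs_d_qs_greater,
        }


def effect_size_summary(d: np.ndarray) -> EffectSizeSummary:
    """Half-open effect-size bins and direction-conditional means.

    Positive D means the edge is greater in active sleep (state coded
    AS = 1); the direction-conditional means are of |D| and exclude exact
    zeros from neither side (D = 0 counts as AS-greater vacuously never:
    zeros contribute to neither directional mean).
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one effect size")
    a = np.abs(d)
    summary = EffectSizeSummary(
        frac_negligible=float(np.mean(a < 0.2)),
        frac_small=float(np.mean((a >= 0.2) & (a < 0.5))),
        frac_medium=float(np.mean((a >= 0.5) & (a < 0.8))),
        frac_large=float(np.mean(a >= 0.8)),
        mean_abs_d_as_greater=float(a[d > 0].mean()) if (d > 0).any() else 0.0,
        mean_abs_d_qs_greater=float(a[d < 0].mean()) if (d < 0).any() else 0.0,
    )
    return summary


def power_analysis(d: float = 0.8, alpha_family: float = 0.05, m_tests: int = 1,
                   power: float = 0.8, method: str = "normal") -> int:
    """Total two-group sample size at a Bonferroni-corrected alpha.

    ``method="normal"``: two-sided two-sample normal approximation,
    ``n_per_group = 2 (z_{1-alpha/2} + z_power)^2 / d^2``.
    ``method="t"``: noncentral-t solve via statsmodels TTestIndPower.
    Returns ``2 * ceil(n_per_group)``.
    """
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be at least 1")
    alpha = alpha_family / m_tests
    if not 0 < alpha < 1:
        raise ValueError("corrected alpha must lie in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive")
    if method == "normal":
        z_a = _stats.norm.ppf(1.0 - alpha / 2.0)
        z_b = _stats.norm.ppf(power)
        n_per_group = 2.0 * (z_a + z_b) ** 2 / d ** 2
    elif method == "t":
        from statsmodels.stats.power import TTestIndPower
        n_per_group = TTestIndPower().solve_power(effect_size=d, alpha=alpha,
                                                  power=power, ratio=1.0,
                                                  alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return 2 * math.ceil(n_per_group - 1e-9)


def calibrate_delta_z(target_d: float, n_as_runs: int, n_qs_runs: int,
                      n_participants: int, n_volumes: int = 90,
                      extra_run_sd: float = 0.0, ols_df: bool = True) -> float:
    """Fisher-z shift whose expected Cohen's D (as estimated by the edge
    model, ``D = 2 t / sqrt(df)``) equals `target_d`.

    The run-level sampling SD of a Fisher-z edge estimate at T volumes is
    approximately ``1/sqrt(T - 3)``; `extra_run_sd` adds (in quadrature) any
    additional between-run variability.  The df matches the fit the data
    will take: OLS residual df when no participant-level variance is
    injected (`ols_df=True`), else the between-within rule.
    """
    n = n_as_runs + n_qs_runs
    s = math.sqrt(1.0 / (n_volumes - 3) + extra_run_sd ** 2)
    df = (n - 2) if ols_df else (n - n_participants - 1)
    expected_t = target_d * math.sqrt(df) / 2.0
    return expected_t * s * math.sqrt(1.0 / n_as_runs + 1.0 / n_qs_runs)
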