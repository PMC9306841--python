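"""Variance-structured regression toolkit for the crowding-stress analysis.

Implements, from first principles, the inferential machinery the colour
analysis needs:

* Wilson score intervals for mortality proportions;
* generalised least squares (GLS) with a per-group residual variance
  structure (a distinct SD ratio per factor level, reference level fixed
  at 1 — "VarIdent");
* linear mixed-effects models (LME) with one or two nested random-intercept
  grouping factors;
* penalized cubic-regression-spline mixed models with an optional
  power-of-the-mean residual variance ("VarPower", Var(e) = s^2 |mu|^(2 delta));
* REML and ML estimation, Wald-F tests and likelihood-ratio tests.

Estimation profiles the fixed effects and the residual scale analytically
and optimises the remaining log-variance parameters by a derivative-free
simplex with three fixed restarts.  REML criteria are comparable across
models with identical fixed effects; likelihood-ratio tests of fixed
effects always use the ML criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "DesignSpec",
    "ModelFit",
    "TestResult",
    "wilson_interval",
    "fit_gls",
    "fit_lme",
    "fit_spline_mixed",
    "predict_smooth",
    "wald_f",
    "lrt",
    "term_dropper",
    "trial_slopes",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------

def wilson_interval(successes: int, n: int, confidence: float = 0.95):
    """Wilson score interval for a binomial proportion.

    Centre (p + z^2/2n) / (1 + z^2/n), half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n), clipped to [0, 1].
    Well behaved at 0 and 1: for zero successes the upper bound is exactly
    z^2 / (n + z^2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    lower = 0.0 if successes == 0 else float(max(0.0, centre - half))
    upper = 1.0 if successes == n else float(min(1.0, centre + half))
    return lower, upper


# ---------------------------------------------------------------------------
# Design specification and encoding
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Model specification over a tidy table.

    ``fixed`` lists term names: a column name (categorical columns get
    treatment contrasts with the alphabetically first level as reference;
    numeric columns enter as-is) or ``"a:b"`` for an interaction of the
    encoded columns.  ``variance_groups`` names a factor column for
    per-level residual SD ratios; ``variance_power`` requests the
    power-of-mean structure instead.  ``random_groups`` gives zero, one or
    two grouping columns; two are treated as nested (outer, inner).
    ``smooth`` names a continuous column modelled by a penalized cubic
    regression spline (used by :func:`fit_spline_mixed`).
    """

    data: pd.DataFrame
    response: str
    fixed: tuple[str, ...] = ()
    variance_groups: str | None = None
    variance_power: bool = False
    random_groups: tuple[str, ...] = ()
    smooth: str | None = None

    def __post_init__(self):
        self.fixed = tuple(self.fixed)
        self.random_groups = tuple(self.random_groups)
        if len(self.random_groups) > 2:
            raise ValueError("at most two (nested) random grouping factors")
        for term in self.fixed:
            for part in term.split(":"):
                if part not in self.data.columns:
                    raise ValueError(f"term {part!r} not in data")
        if self.response not in self.data.columns:
            raise ValueError(f"response {self.response!r} not in data")

    def drop_term(self, term: str) -> "DesignSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in fixed effects")
        # also drop interactions referencing the term
        keep = tuple(
            t for t in self.fixed if t != term and term not in t.split(":")
        )
        return replace(self, fixed=keep)


def _is_categorical(col: pd.Series) -> bool:
    return (
        col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == bool
    )


def _encode_main(data: pd.DataFrame, name: str):
    col = data[name]
    if _is_categorical(col):
        levels = sorted(pd.unique(col.astype(str)))
        cols = [(f"{name}[T.{lv}]", (col.astype(str) == lv).to_numpy(float))
                for lv in levels[1:]]
        return cols
    return [(name, col.to_numpy(float))]


def _encode_term(data: pd.DataFrame, term: str):
    parts = term.split(":")
    cols = _encode_main(data, parts[0])
    for part in parts[1:]:
        nxt = _encode_main(data, part)
        cols = [(f"{n1}:{n2}", v1 * v2) for n1, v1 in cols for n2, v2 in nxt]
    return cols


def build_design(spec: DesignSpec):
    """Encode the fixed effects: returns (X, names, term_cols, y)."""
    names = ["Intercept"]
    columns = [np.ones(len(spec.data))]
    term_cols: dict[str, list[str]] = {}
    for term in spec.fixed:
        encoded = _encode_term(spec.data, term)
        term_cols[term] = [n for n, _ in encoded]
        for n, v in encoded:
            names.append(n)
            columns.append(v)
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effects design")
    y = spec.data[spec.response].to_numpy(float)
    return X, names, term_cols, y


def _group_codes(data: pd.DataFrame, name: str):
    col = data[name].astype(str)
    levels = sorted(pd.unique(col))
    codes = col.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    return codes, levels


# ---------------------------------------------------------------------------
# Fit container and tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_type: str  # "wald_f" or "lrt"
    df_denom: int | None = None


@dataclass
class ModelFit:
    """A fitted GLS / LME / spline-mixed model."""

    method: str
    params: pd.Series
    cov_params: pd.DataFrame
    sigma: float
    var_ratios: dict[str, float]
    var_power: float | None
    random_sd: dict[str, float]
    loglik_reml: float
    loglik_ml: float
    converged: bool
    n_obs: int
    term_cols: dict[str, list[str]]
    spec: DesignSpec
    extra: dict = field(default_factory=dict)

    @property
    def df_fixed(self) -> int:
        return len(self.params)

    @property
    def n_param(self) -> int:
        """Total parameter count: fixed + variance params + residual scale."""
        n_var = max(0, len(self.var_ratios) - 1) if self.var_ratios else 0
        n_var += len(self.random_sd)
        n_var += 1 if self.var_power is not None else 0
        return self.df_fixed + n_var + 1

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)


def wald_f(fit: ModelFit, term: str) -> TestResult:
    """Wald F test for dropping ``term`` from a fitted model.

    F = (L b)' (L V L')^{-1} (L b) / q with L the identity contrast on the
    term's coefficients; the reference distribution is F(q, n - p).
    """
    if term not in fit.term_cols:
        raise ValueError(f"term {term!r} not in fit")
    cols = fit.term_cols[term]
    b = fit.params[cols].to_numpy()
    V = fit.cov_params.loc[cols, cols].to_numpy()
    q = len(cols)
    try:
        sol = np.linalg.solve(V, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance") from exc
    F = float(b @ sol / q)
    df2 = fit.n_obs - fit.df_fixed
    p = float(sps.f.sf(F, q, df2))
    return TestResult(statistic=F, df=q, p_value=p, test_type="wald_f", df_denom=df2)


def lrt(fit_full: ModelFit, fit_reduced: ModelFit) -> TestResult:
    """Likelihood-ratio test of nested models using their ML log-likelihoods.

    Nesting is checked on the fixed-term sets; the degrees of freedom are
    the difference in total parameter counts.
    """
    full_terms = set(fit_full.term_cols)
    red_terms = set(fit_reduced.term_cols)
    if not red_terms <= full_terms:
        raise ValueError("models are not nested (reduced has terms absent from full)")
    df = fit_full.n_param - fit_reduced.n_param
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    stat = max(0.0, 2.0 * (fit_full.loglik_ml - fit_reduced.loglik_ml))
    df_eff = max(df, 1)
    p = float(sps.chi2.sf(stat, df_eff)) if df > 0 else 1.0
    return TestResult(statistic=float(stat), df=df_eff, p_value=p, test_type="lrt")


# ---------------------------------------------------------------------------
# Optimiser helper: derivative-free simplex with fixed restarts
# ---------------------------------------------------------------------------

_RESTART_SHIFTS = (0.0, 0.7, -0.7)


def _optimize(objective, x0):
    x0 = np.asarray(x0, dtype=float)
    if x0.size == 0:
        return x0, objective(x0), True
    best = None
    for shift in _RESTART_SHIFTS:
        res = optimize.minimize(
            objective, x0 + shift, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, best.fun, bool(best.success)


# ---------------------------------------------------------------------------
# GLS with per-group variance ratios
# ---------------------------------------------------------------------------

def _gls_criteria(X, y, codes, logdelta):
    """(-2 REML, -2 ML, components) for VarIdent GLS at given log SD ratios."""
    n, p = X.shape
    delta = np.concatenate([[1.0], np.exp(logdelta)])
    w = 1.0 / delta[codes] ** 2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdetV = float(-2.0 * np.sum(np.log(sw)))
    _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
    s2_reml = rss / (n - p)
    s2_ml = rss / n
    m2_reml = (n - p) * (np.log(s2_reml) + _LOG2PI + 1.0) + logdetV + logdet_xtx
    m2_ml = n * (np.log(s2_ml) + _LOG2PI + 1.0) + logdetV
    return m2_reml, m2_ml, (beta, rss, delta, w)


def fit_gls(spec: DesignSpec) -> ModelFit:
    """REML GLS with a per-group residual variance structure.

    With a single variance group (or none) this reduces exactly to ordinary
    least squares.  The SD ratios delta_g (reference level 1) are estimated
    by numerically maximising the profiled REML criterion over log delta;
    the ML criterion is maximised separately for use in likelihood-ratio
    tests.
    """
    X, names, term_cols, y = build_design(spec)
    n, p = X.shape
    if spec.variance_groups is not None:
        codes, levels = _group_codes(spec.data, spec.variance_groups)
    else:
        codes, levels = np.zeros(n, dtype=int), ["all"]
    G = len(levels)

    converged = True
    if G == 1:
        m2_reml, m2_ml, (beta, rss, delta, w) = _gls_criteria(X, y, codes, np.empty(0))
    else:
        x0 = np.zeros(G - 1)
        xr, fr, ok_r = _optimize(lambda ld: _gls_criteria(X, y, codes, ld)[0], x0)
        xm, fm, ok_m = _optimize(lambda ld: _gls_criteria(X, y, codes, ld)[1], x0)
        converged = ok_r and ok_m
        m2_reml, _, (beta, rss, delta, w) = _gls_criteria(X, y, codes, xr)
        _, m2_ml, _ = _gls_criteria(X, y, codes, xm)

    s2 = rss / (n - p)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    return ModelFit(
        method="gls",
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma=float(np.sqrt(s2)),
        var_ratios={lv: float(d) for lv, d in zip(levels, delta)} if G > 1 else {},
        var_power=None,
        random_sd={},
        loglik_reml=-0.5 * float(m2_reml),
        loglik_ml=-0.5 * float(m2_ml),
        converged=converged,
        n_obs=n,
        term_cols=term_cols,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Linear mixed-effects model with nested random intercepts
# ---------------------------------------------------------------------------

def _random_design(spec: DesignSpec):
    """Indicator matrices for the random-intercept groupings (nested)."""
    Zs, labels = [], []
    combined = None
    for gname in spec.random_groups:
        col = spec.data[gname].astype(str)
        combined = col if combined is None else combined + "/" + col
        codes, levels = _group_codes(combined.to_frame(name="g"), "g")
        if len(levels) < 2:
            raise ValueError(f"grouping factor {gname!r} needs >= 2 levels")
        Z = np.zeros((len(codes), len(levels)))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
        labels.append(gname)
    return Zs, labels


class _CSolver:
    """Solver for C = D + sum_k gam_k^2 Z_k Z_k' via the Woodbury identity.

    Work happens in the q-dimensional random-effects space (q = total
    random-effect columns), which is far smaller than n; stable as the
    variance ratios go to zero.
    """

    def __init__(self, d, Zs, gam):
        self.d = d
        self.w = 1.0 / d
        if Zs:
            S = np.hstack([g * Z for g, Z in zip(gam, Zs)])  # n x q
            WS = S * self.w[:, None]
            M = np.eye(S.shape[1]) + S.T @ WS
            self._cf = cho_factor(M, lower=True)
            self._S, self._WS = S, WS
            self.logdet = float(np.sum(np.log(d))) + 2.0 * float(
                np.sum(np.log(np.diag(self._cf[0])))
            )
        else:
            self._S = None
            self.logdet = float(np.sum(np.log(d)))

    def solve(self, b):
        wb = self.w[:, None] * b if b.ndim == 2 else self.w * b
        if self._S is None:
            return wb
        t = cho_solve(self._cf, self._S.T @ wb)
        return wb - self._WS @ t


def _lme_criteria(X, y, codes, Zs, theta, n_delta, *, diag_extra=None):
    """Profiled (-2 REML, -2 ML, parts) for the mixed model.

    ``theta`` stacks log SD ratios for the VarIdent groups (n_delta of them)
    then log(tau_k / sigma) for each random grouping.  The marginal relative
    covariance is C = D + sum_k (tau_k/sigma)^2 Z_k Z_k'.
    """
    n, p = X.shape
    logdelta = theta[:n_delta]
    loggam = np.clip(theta[n_delta:], -8.0, 8.0)
    delta = np.concatenate([[1.0], np.exp(logdelta)])
    d = delta[codes] ** 2
    if diag_extra is not None:
        d = d * diag_extra
    gam = np.exp(loggam)
    try:
        cs = _CSolver(d, Zs, gam)
        CiX = cs.solve(X)
        XtCiX = X.T @ CiX
        beta = np.linalg.solve(XtCiX, X.T @ cs.solve(y))
    except np.linalg.LinAlgError:
        return np.inf, np.inf, None
    r = y - X @ beta
    rss = float(r @ cs.solve(r))
    if rss <= 0:
        return np.inf, np.inf, None
    _, logdet_xtx = np.linalg.slogdet(XtCiX)
    s2_reml = rss / (n - p)
    s2_ml = rss / n
    m2_reml = (n - p) * (np.log(s2_reml) + _LOG2PI + 1.0) + cs.logdet + logdet_xtx
    m2_ml = n * (np.log(s2_ml) + _LOG2PI + 1.0) + cs.logdet
    parts = (beta, rss, gam, delta, cs, XtCiX)
    return m2_reml, m2_ml, parts


def fit_lme(spec: DesignSpec) -> ModelFit:
    """REML linear mixed model with random intercepts (one or two nested
    grouping factors) and an optional per-group residual variance structure.

    The fixed effects and residual scale are profiled analytically; the
    remaining log-variance parameters are optimised by simplex.  Singular
    fits are reported with the corresponding tau-hat near zero rather than
    raised.
    """
    if not spec.random_groups:
        raise ValueError("fit_lme requires at least one random grouping factor")
    X, names, term_cols, y = build_design(spec)
    n, p = X.shape
    if spec.variance_groups is not None:
        codes, levels = _group_codes(spec.data, spec.variance_groups)
    else:
        codes, levels = np.zeros(n, dtype=int), ["all"]
    G = len(levels)
    Zs, labels = _random_design(spec)
    n_delta = G - 1

    x0 = np.concatenate([np.zeros(n_delta), np.full(len(Zs), -0.5)])
    xr, fr, ok_r = _optimize(lambda t: _lme_criteria(X, y, codes, Zs, t, n_delta)[0], x0)
    xm, fm, ok_m = _optimize(lambda t: _lme_criteria(X, y, codes, Zs, t, n_delta)[1], x0)
    m2_reml, _, parts = _lme_criteria(X, y, codes, Zs, xr, n_delta)
    _, m2_ml, _ = _lme_criteria(X, y, codes, Zs, xm, n_delta)
    beta, rss, gam, delta, _, XtCiX = parts

    s2 = rss / (n - p)
    sigma = float(np.sqrt(s2))
    cov = s2 * np.linalg.inv(XtCiX)
    random_sd = {lab: float(g * sigma) for lab, g in zip(labels, gam)}
    return ModelFit(
        method="lme",
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma=sigma,
        var_ratios={lv: float(d) for lv, d in zip(levels, delta)} if G > 1 else {},
        var_power=None,
        random_sd=random_sd,
        loglik_reml=-0.5 * float(m2_reml),
        loglik_ml=-0.5 * float(m2_ml),
        converged=ok_r and ok_m,
        n_obs=n,
        term_cols=term_cols,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Penalized cubic regression spline mixed model (GAMM-style)
# ---------------------------------------------------------------------------

def _spline_basis(x, k):
    """Cubic B-spline basis with k functions, knots at quantiles of x.

    Returns (B, knots).  Requires k >= 4 distinct-enough data.
    """
    if k < 4:
        raise ValueError("basis dimension must be >= 4")
    xl, xu = float(np.min(x)), float(np.max(x))
    span = xu - xl
    if span <= 0:
        raise ValueError("smooth covariate is constant")
    xl -= 1e-8 * span
    xu += 1e-8 * span
    if k > 4:
        interior = np.quantile(x, np.linspace(0, 1, k - 2)[1:-1])
        interior = np.clip(interior, xl + 1e-10, xu - 1e-10)
    else:
        interior = np.empty(0)
    knots = np.concatenate([[xl] * 4, interior, [xu] * 4])
    if np.unique(knots).size != k - 2:
        raise ValueError("smooth covariate has too few distinct values for this basis")
    B = BSpline.design_matrix(np.clip(x, xl, xu), knots, 3).toarray()
    return B, knots


def _spline_penalty(knots, k, n_grid=1024):
    """Integrated squared second-derivative penalty matrix (k x k)."""
    xs = np.linspace(knots[0], knots[-1], n_grid)
    D2 = np.empty((n_grid, k))
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        D2[:, j] = BSpline(knots, c, 3).derivative(2)(xs)
    w = np.full(n_grid, knots[-1] - knots[0]) / (n_grid - 1)
    w[0] *= 0.5
    w[-1] *= 0.5
    return (D2 * w[:, None]).T @ D2


def _smooth_reparam(B, S):
    """Split a penalized basis into unpenalized and whitened penalized parts.

    Eigen-decomposes S; null-space columns (constants/linears, already
    spanned by the parametric intercept + linear term) are dropped, and the
    penalized range is scaled so the penalty becomes the identity — i.e. the
    spline wiggles enter as iid random effects.
    """
    lam, U = np.linalg.eigh(S)
    tol = lam[-1] * 1e-9
    pos = lam > tol
    Br = B @ U[:, pos] / np.sqrt(lam[pos])
    return Br, U[:, pos], lam[pos]


def fit_spline_mixed(spec: DesignSpec, basis_dims=(4, 5, 6, 8, 10, 12),
                     max_outer: int = 10, tol: float = 1e-5) -> ModelFit:
    """Penalized cubic regression spline with mixed-model smoothing.

    The smooth f(x) is represented as (intercept +) linear term plus
    penalized wiggle coefficients treated as iid Gaussian random effects
    whose variance (the inverse smoothing parameter) is estimated by REML
    alongside any random-intercept groupings.  The basis dimension is chosen
    by ML AIC with effective degrees of freedom (trace of the influence
    matrix), not raw basis size.  With ``spec.variance_power`` the residual
    variance follows sigma^2 |mu|^(2 delta), estimated by iterating the
    variance fit against the fitted mean (floored at 1e-6).
    """
    if spec.smooth is None:
        raise ValueError("spec.smooth must name the spline covariate")
    x = spec.data[spec.smooth].to_numpy(float)
    parametric = tuple(t for t in spec.fixed if spec.smooth not in t.split(":"))
    base_spec = replace(spec, fixed=parametric)
    X0, names0, term_cols, y = build_design(base_spec)
    n = len(y)
    xc = x - x.mean()
    X = np.column_stack([X0, xc])
    names = names0 + [spec.smooth]
    term_cols = dict(term_cols)
    term_cols[spec.smooth] = [spec.smooth]

    Zs_groups, labels = _random_design(spec) if spec.random_groups else ([], [])
    codes = np.zeros(n, dtype=int)  # VarIdent not combined with VarPower here

    best = None
    for k in basis_dims:
        if np.unique(x).size < k:
            continue
        try:
            B, knots = _spline_basis(x, k)
        except ValueError:
            continue
        S = _spline_penalty(knots, k)
        Br, Upos, lampos = _smooth_reparam(B, S)
        Zs = [Br] + Zs_groups
        fit_k = _fit_spline_at_k(X, y, Zs, spec.variance_power, max_outer, tol)
        if fit_k is None:
            continue
        aic = fit_k["m2_ml"] + 2.0 * (fit_k["edf"] + fit_k["n_varpar"])
        if best is None or aic < best["aic"]:
            best = dict(fit_k, aic=aic, k=k, knots=knots, Upos=Upos,
                        lampos=lampos, Br=Br)
    if best is None:
        raise ValueError("no basis dimension could be fitted")

    sigma = float(np.sqrt(best["s2"]))
    gam = best["gam"]
    random_sd = {"smooth": float(gam[0] * sigma)}
    random_sd.update({lab: float(g * sigma) for lab, g in zip(labels, gam[1:])})
    beta = best["beta"]
    cov = best["cov_beta"]
    return ModelFit(
        method="spline",
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma=sigma,
        var_ratios={},
        var_power=best["delta_power"],
        random_sd=random_sd,
        loglik_reml=-0.5 * best["m2_reml"],
        loglik_ml=-0.5 * best["m2_ml"],
        converged=best["converged"],
        n_obs=n,
        term_cols=term_cols,
        spec=spec,
        extra={
            "basis_dim": best["k"],
            "knots": best["knots"],
            "Upos": best["Upos"],
            "lampos": best["lampos"],
            "u_smooth": best["u"][0],
            "u_groups": best["u"][1:],
            "edf": best["edf"],
            "smooth_edf": best["smooth_edf"],
            "aic": best["aic"],
            "x_mean": float(x.mean()),
            "coef_cov_full": best["cov_full"],
            "smooth_col_index": len(names) - 1,
        },
    )


def _fit_spline_at_k(X, y, Zs, use_varpower, max_outer, tol):
    """Inner estimation at one basis dimension; returns a dict of results."""
    n, p = X.shape
    codes = np.zeros(n, dtype=int)
    mu = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    delta_power = 0.0
    converged = False
    parts_out = None
    xr = None
    for outer in range(max_outer if use_varpower else 1):
        mu_abs = np.maximum(np.abs(mu), 1e-6)

        def crit(theta, which):
            if use_varpower:
                diag = mu_abs ** (2.0 * np.clip(theta[0], -5.0, 5.0))
                t_rest = theta[1:]
            else:
                diag, t_rest = None, theta
            m2r, m2m, _ = _lme_criteria(X, y, codes, Zs, t_rest, 0, diag_extra=diag)
            return m2r if which == 0 else m2m

        x0 = (np.concatenate([[delta_power], np.full(len(Zs), -0.5)])
              if use_varpower else np.full(len(Zs), -0.5)) if xr is None else xr
        xr, fr, ok_r = _optimize(lambda t: crit(t, 0), x0)
        if use_varpower:
            delta_power_new = float(np.clip(xr[0], -5.0, 5.0))
            theta_r = xr[1:]
        else:
            delta_power_new = None
            theta_r = xr
        diag_r = mu_abs ** (2.0 * delta_power_new) if use_varpower else None
        m2_reml, _, parts = _lme_criteria(X, y, codes, Zs, theta_r, 0, diag_extra=diag_r)
        if parts is None:
            return None
        beta, rss, gam, _, cs, XtCiX = parts
        # BLUPs: u_k = gam_k^2 Z_k' C^{-1} r
        r = y - X @ beta
        Cir = cs.solve(r)
        u = [g * g * (Z.T @ Cir) for g, Z in zip(gam, Zs)]
        mu_new = X @ beta + sum(Z @ uk for Z, uk in zip(Zs, u))
        shift = float(np.max(np.abs(mu_new - mu))) / (float(np.std(y)) + 1e-12)
        mu = mu_new
        if use_varpower:
            delta_power = delta_power_new
        parts_out = (beta, rss, gam, XtCiX, u, m2_reml, ok_r)
        if not use_varpower or shift < tol:
            converged = True
            break
    if parts_out is None:
        return None
    beta, rss, gam, XtCiX, u, m2_reml, opt_ok = parts_out

    # ML pass at the converged working weights (used for AIC / LRTs)
    mu_abs = np.maximum(np.abs(mu), 1e-6)

    def crit_ml(theta):
        if use_varpower:
            diag = mu_abs ** (2.0 * np.clip(theta[0], -5.0, 5.0))
            t_rest = theta[1:]
        else:
            diag, t_rest = None, theta
        return _lme_criteria(X, y, codes, Zs, t_rest, 0, diag_extra=diag)[1]

    xm, m2_ml, ok_m = _optimize(crit_ml, xr)
    opt_ok = opt_ok and ok_m

    s2 = rss / (n - p)
    cov_beta = s2 * np.linalg.inv(XtCiX)

    # Effective degrees of freedom: trace of the influence matrix of the
    # joint penalized system [X | Z...] with ridge I/gam_k^2 per block.
    mu_abs = np.maximum(np.abs(mu), 1e-6)
    w = 1.0 / (mu_abs ** (2.0 * delta_power)) if use_varpower else np.ones(n)
    M = np.column_stack([X] + Zs)
    pen = np.concatenate(
        [np.zeros(p)] + [np.full(Z.shape[1], 1.0 / max(g, 1e-8) ** 2)
                         for Z, g in zip(Zs, gam)]
    )
    MtWM = (M * w[:, None]).T @ M
    A = np.linalg.solve(MtWM + np.diag(pen), MtWM)
    edf = float(np.trace(A))
    q_s = Zs[0].shape[1]
    smooth_edf = 1.0 + float(np.trace(A[p : p + q_s, p : p + q_s]))
    cov_full = s2 * np.linalg.inv(MtWM + np.diag(pen))
    n_varpar = len(Zs) + (1 if use_varpower else 0) + 1
    return {
        "beta": beta, "gam": gam, "u": u, "s2": s2, "cov_beta": cov_beta,
        "m2_reml": float(m2_reml), "m2_ml": float(m2_ml), "edf": edf,
        "smooth_edf": smooth_edf, "cov_full": cov_full,
        "delta_power": (delta_power if use_varpower else None),
        "converged": converged and opt_ok, "n_varpar": n_varpar,
    }


def predict_smooth(fit: ModelFit, xnew, se: bool = False):
    """Evaluate the fitted smooth (population level) at new covariate values.

    Returns the fitted curve, optionally with pointwise standard errors from
    the joint coefficient covariance (intercept + linear + wiggles).
    """
    if fit.method != "spline":
        raise ValueError("predict_smooth requires a spline fit")
    ex = fit.extra
    xnew = np.asarray(xnew, dtype=float)
    knots = ex["knots"]
    k = ex["basis_dim"]
    xcl = np.clip(xnew, knots[0], knots[-1])
    B = BSpline.design_matrix(xcl, knots, 3).toarray()
    Br = B @ ex["Upos"] / np.sqrt(ex["lampos"])
    beta = fit.params.to_numpy()
    icol = ex["smooth_col_index"]
    eta = beta[0] + beta[icol] * (xcl - ex["x_mean"]) + Br @ ex["u_smooth"]
    if not se:
        return eta
    p = len(beta)
    q_s = Br.shape[1]
    C = np.zeros((len(xcl), ex["coef_cov_full"].shape[0]))
    C[:, 0] = 1.0
    C[:, icol] = xcl - ex["x_mean"]
    C[:, p : p + q_s] = Br
    var = np.einsum("ij,jk,ik->i", C, ex["coef_cov_full"], C)
    return eta, np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# Model-selection helper and reporting
# ---------------------------------------------------------------------------

def term_dropper(spec: DesignSpec, term: str = "vitality_assessed",
                 alpha: float = 0.05, fitter=fit_gls, test: str = "wald"):
    """Drop ``term`` from the model if it is not significant at ``alpha``.

    Fits the full model, tests the term (Wald-F for GLS, LRT otherwise),
    and returns ``(chosen_spec, chosen_fit, audit)`` where the audit record
    documents the decision.
    """
    if term not in spec.fixed:
        return spec, fitter(spec), {"term": term, "present": False, "dropped": False}
    fit_full = fitter(spec)
    if test == "wald":
        res = wald_f(fit_full, term)
    else:
        fit_red_ml = fitter(spec.drop_term(term))
        res = lrt(fit_full, fit_red_ml)
    audit = {
        "term": term, "present": True, "p_value": res.p_value,
        "statistic": res.statistic, "test": res.test_type, "alpha": alpha,
    }
    if res.p_value >= alpha:
        reduced = spec.drop_term(term)
        audit["dropped"] = True
        return reduced, fitter(reduced), audit
    audit["dropped"] = False
    return spec, fit_full, audit


def trial_slopes(fit: ModelFit, trial_col: str = "trial",
                 exposure_col: str = "exposure_min") -> pd.DataFrame:
    """Per-trial exposure slopes (b* units per minute) from a trial-by-
    exposure fit, with standard errors from the coefficient covariance."""
    inter = f"{trial_col}:{exposure_col}"
    if exposure_col not in fit.term_cols:
        raise ValueError("fit has no exposure main effect")
    base = exposure_col
    cov = fit.cov_params
    rows = []
    levels = sorted(pd.unique(fit.spec.data[trial_col].astype(str)))
    for lv in levels:
        cols = [base]
        iname = f"{trial_col}[T.{lv}]:{exposure_col}"
        if inter in fit.term_cols and iname in fit.params.index:
            cols.append(iname)
        slope = float(fit.params[cols].sum())
        v = float(cov.loc[cols, cols].to_numpy().sum())
        rows.append((lv, slope, np.sqrt(v)))
    return pd.DataFrame(rows, columns=[trial_col, "slope", "se"])
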