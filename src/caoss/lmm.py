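"""Linear mixed models with crossed random intercepts, fitted by ML.

The model is

    y = X beta + Z1 u1 + Z2 u2 + e,
    u1 ~ N(0, tau1^2 I),  u2 ~ N(0, tau2^2 I),  e ~ N(0, sigma^2 I),

with the two grouping factors (first and second constituent character)
*crossed*, not nested.  Estimation is maximum likelihood (REML is
available behind a flag for sensitivity checks, but all reported
analyses use ML).

Implementation notes
--------------------
Let gamma_k = tau_k^2 / sigma^2 and Z = [Z1 Z2] (n x q).  With
V0 = I + Z D Z', D = diag(gamma_1 I_q1, gamma_2 I_q2), the Woodbury
identity reduces every likelihood evaluation to q x q linear algebra:

    V0^{-1} = I - Z D^{1/2} M^{-1} D^{1/2} Z',   M = I_q + D^{1/2} Z'Z D^{1/2},
    log|V0| = log|M|.

beta and sigma^2 are profiled out analytically, leaving a 1- or
2-dimensional optimization over log gamma, done by Nelder-Mead from
three fixed starting points (the likelihood in crossed designs can be
mildly multimodal near the boundary).

Satterthwaite denominator df use the delta method: with theta =
(tau1^2, tau2^2, sigma^2),

    df_j = 2 [C_jj(theta)]^2 / (g_j' A g_j),

where C = sigma^2 (X'V0^{-1}X)^{-1} is the covariance of beta-hat,
g_j = dC_jj/dtheta (central differences), and A is the inverse observed
information of theta from the beta-profiled log-likelihood (numerical
Hessian).  When the information matrix is not invertible the df fall
back to the OLS value n - p with a logged downgrade notice.

Semipartial R^2 per fixed effect uses the single-predictor
Edwards-style mapping R^2 = F / (F + df) with F = t^2 and df the
coefficient's Satterthwaite denominator df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = ["FixedEffect", "AnalysisResult", "LMMConvergenceError", "fit_lmm",
           "semipartial_r2_from_t"]


def semipartial_r2_from_t(t: float, df: float) -> float:
    """Edwards-style semipartial R^2 for one fixed effect.

    With numerator df 1, F = t^2 and R^2 = (F/df) / (1 + F/df) = F / (F + df),
    df being the coefficient's Satterthwaite denominator df.
    """
    if df <= 0 or not np.isfinite(df):
        raise ValueError("denominator df must be positive and finite")
    F = float(t) ** 2
    return F / (F + df)

_LOG_GAMMA_MIN = -30.0  # gamma below exp(-30) is numerically zero
_SINGULAR_GAMMA = 1e-6


class LMMConvergenceError(RuntimeError):
    """Raised when no optimizer start converged; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float
    semipartial_r2: float | None  # None for the intercept


@dataclass
class AnalysisResult:
    """One fitted mixed model: coefficient table plus fit bookkeeping."""

    fixed_effects: list[FixedEffect]
    var_components: dict[str, float]  # grouping factor -> intercept variance
    var_resid: float
    loglik: float
    n_items: int
    n_params: int  # fixed effects + variance components + residual
    converged: bool = True
    singular: bool = False
    reml: bool = False
    model_label: str = ""
    notes: list[str] = field(default_factory=list)
    optimizer: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (fe.name, fe.estimate, fe.se, fe.t, fe.df, fe.p, fe.semipartial_r2)
                for fe in self.fixed_effects
            ],
            columns=["predictor", "estimate", "se", "t", "df", "p", "semipartial_r2"],
        )

    def to_dict(self) -> dict:
        return {
            "model_label": self.model_label,
            "fixed_effects": [
                {
                    "name": fe.name, "estimate": fe.estimate, "se": fe.se,
                    "t": fe.t, "df": fe.df, "p": fe.p,
                    "semipartial_r2": fe.semipartial_r2,
                }
                for fe in self.fixed_effects
            ],
            "var_components": self.var_components,
            "var_resid": self.var_resid,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_items": self.n_items,
            "n_params": self.n_params,
            "converged": self.converged,
            "singular": self.singular,
            "notes": self.notes,
        }


class _LMMData:
    """Precomputed sufficient statistics for the Woodbury likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_codes: list[np.ndarray]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.sizes = [int(g.max()) + 1 for g in group_codes]
        self.q = sum(self.sizes)
        # Z'Z, Z'X, Z'y assembled blockwise; Z columns ordered factor by factor.
        Zt_rows = []
        offs = np.cumsum([0] + self.sizes)
        ZtZ = np.zeros((self.q, self.q))
        ZtX = np.zeros((self.q, self.p))
        Zty = np.zeros(self.q)
        for a, ga in enumerate(group_codes):
            ia = offs[a] + ga
            np.add.at(ZtX, ia, X)
            np.add.at(Zty, ia, y)
            for b, gb in enumerate(group_codes):
                block = np.zeros((self.sizes[a], self.sizes[b]))
                np.add.at(block, (ga, gb), 1.0)
                ZtZ[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = block
        self.ZtZ, self.ZtX, self.Zty = ZtZ, ZtX, Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.offs = offs

    def _pieces(self, gammas: np.ndarray):
        """GLS pieces at variance ratios gamma: (XtVX, XtVy, yVy, logdetM)."""
        s = np.concatenate([np.full(sz, np.sqrt(max(g, 0.0))) for sz, g in zip(self.sizes, gammas)])
        M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        L = cho_factor(M, lower=True)
        sZtX = s[:, None] * self.ZtX
        sZty = s * self.Zty
        U = cho_solve(L, sZtX)
        u = cho_solve(L, sZty)
        XtVX = self.XtX - sZtX.T @ U
        XtVy = self.Xty - sZtX.T @ u
        yVy = self.yty - float(sZty @ u)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        return XtVX, XtVy, yVy, logdetM

    def profile_nll(self, log_gammas: np.ndarray, reml: bool = False) -> float:
        """Negative profile log-likelihood over (beta, sigma^2)."""
        gammas = np.exp(np.clip(log_gammas, _LOG_GAMMA_MIN, 30.0))
        try:
            XtVX, XtVy, yVy, logdetM = self._pieces(gammas)
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf
        rVr = max(yVy - float(beta @ XtVy), 1e-300)
        n, p = self.n, self.p
        if reml:
            sigma2 = rVr / (n - p)
            sign, logdetXtVX = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return np.inf
            ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdetM + logdetXtVX)
        else:
            sigma2 = rVr / n
            ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetM)
        return -ll

    def loglik_at(self, theta: np.ndarray) -> float:
        """Log-likelihood at theta = (tau^2 per factor..., sigma^2), beta profiled."""
        sigma2 = theta[-1]
        if sigma2 <= 0 or np.any(theta[:-1] < 0):
            return -np.inf
        gammas = theta[:-1] / sigma2
        XtVX, XtVy, yVy, logdetM = self._pieces(gammas)
        beta = np.linalg.solve(XtVX, XtVy)
        rVr = yVy - float(beta @ XtVy)
        return -0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdetM + rVr / sigma2)

    def beta_cov_diag(self, theta: np.ndarray) -> np.ndarray:
        """diag of Cov(beta-hat) = sigma^2 (X'V0^{-1}X)^{-1} at theta."""
        sigma2 = theta[-1]
        gammas = np.maximum(theta[:-1], 0.0) / sigma2
        XtVX, *_ = self._pieces(gammas)
        return sigma2 * np.diag(np.linalg.inv(XtVX))

    def gls(self, gammas: np.ndarray, reml: bool = False):
        XtVX, XtVy, yVy, logdetM = self._pieces(gammas)
        beta = np.linalg.solve(XtVX, XtVy)
        rVr = max(yVy - float(beta @ XtVy), 0.0)
        sigma2 = rVr / (self.n - self.p if reml else self.n)
        cov = sigma2 * np.linalg.inv(XtVX)
        return beta, sigma2, cov


def _numerical_hessian(f, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _satterthwaite(data: _LMMData, theta_hat: np.ndarray, notes: list[str]) -> np.ndarray:
    """Per-coefficient Satterthwaite denominator df via the delta method.

    Variance components estimated at the boundary (tau^2 ~ 0) are not
    interior parameters: their sampling distribution is not locally
    quadratic, so they are held fixed at zero and excluded from the
    delta-method parameter vector rather than differenced across zero.
    """
    n, p = data.n, data.p
    sigma2 = theta_hat[-1]
    k = len(theta_hat)
    active = [i for i in range(k - 1) if theta_hat[i] > _SINGULAR_GAMMA * sigma2] + [k - 1]
    if len(active) < k:
        notes.append("satterthwaite: boundary variance component(s) held at zero")
    idx = np.array(active)
    th0 = theta_hat[idx]
    h = 1e-3 * np.abs(th0)

    def embed(t_active: np.ndarray) -> np.ndarray:
        full = np.zeros(k)
        full[idx] = t_active
        return full

    try:
        H = _numerical_hessian(lambda t: -data.loglik_at(embed(t)), th0, h)
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        notes.append("satterthwaite: information matrix not invertible, df downgraded to n - p")
        logger.warning("Satterthwaite downgrade: information not invertible")
        return np.full(p, float(n - p))

    C0 = data.beta_cov_diag(theta_hat)
    grads = np.zeros((p, len(idx)))
    for i in range(len(idx)):
        ei = np.zeros(len(idx)); ei[i] = h[i]
        grads[:, i] = (
            data.beta_cov_diag(embed(th0 + ei)) - data.beta_cov_diag(embed(th0 - ei))
        ) / (2 * h[i])

    dfs = np.empty(p)
    for j in range(p):
        denom = float(grads[j] @ A @ grads[j])
        if denom <= 0 or not np.isfinite(denom):
            dfs[j] = float(n - p)
            notes.append(f"satterthwaite: nonpositive variance-of-variance for coefficient {j}, df = n - p")
        else:
            dfs[j] = 2.0 * C0[j] ** 2 / denom
    return dfs


_STARTS = {
    1: [np.array([-1.5]), np.array([0.5]), np.array([-6.0])],
    2: [np.array([-1.5, -1.5]), np.array([0.5, 0.5]), np.array([-6.0, -6.0])],
}


def fit_lmm(
    design: pd.DataFrame,
    dv: str,
    fixed: list[str],
    groups: tuple[str, ...] = ("c1", "c2"),
    reml: bool = False,
    add_intercept: bool = True,
    model_label: str = "",
) -> AnalysisResult:
    """Fit a crossed-random-intercept linear mixed model by ML.

    Parameters
    ----------
    design:
        One row per item; must contain `dv`, every column in `fixed`,
        and the grouping columns in `groups`.
    fixed:
        Fixed-effect predictor columns (an intercept is prepended unless
        ``add_intercept=False``).
    groups:
        One or two grouping-factor columns; each must have >= 2 levels.

    Raises
    ------
    LMMConvergenceError
        If no optimizer start converges; the exception carries the
        per-start diagnostics.
    """
    y = design[dv].to_numpy(dtype=float)
    cols = [np.ones(len(design))] if add_intercept else []
    names = ["intercept"] if add_intercept else []
    for f in fixed:
        cols.append(design[f].to_numpy(dtype=float))
        names.append(f)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    group_codes = []
    for g in groups:
        codes, levels = pd.factorize(design[g])
        if len(levels) < 2:
            raise ValueError(f"grouping factor {g!r} has fewer than 2 levels")
        group_codes.append(codes.astype(np.int64))

    data = _LMMData(y, X, group_codes)
    k = len(groups)

    best = None
    diag = []
    for x0 in _STARTS[k]:
        res = optimize.minimize(
            data.profile_nll, x0, args=(reml,), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000, "maxfev": 4000},
        )
        diag.append({"x0": x0.tolist(), "x": res.x.tolist(), "fun": float(res.fun),
                     "success": bool(res.success), "nfev": int(res.nfev)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise LMMConvergenceError("all optimizer starts failed", {"starts": diag})
    converged = any(d["success"] for d in diag)
    if not converged:
        raise LMMConvergenceError("optimizer did not converge from any start", {"starts": diag})

    gammas = np.exp(np.clip(best.x, _LOG_GAMMA_MIN, 30.0))
    beta, sigma2, cov = data.gls(gammas, reml=reml)
    taus = gammas * sigma2
    theta_hat = np.concatenate([taus, [sigma2]])

    notes: list[str] = []
    singular = bool(np.any(gammas < _SINGULAR_GAMMA))
    if singular:
        notes.append("singular fit: at least one random-intercept variance estimated at ~0")
        logger.info("singular fit for %s: gammas=%s", model_label or dv, gammas)

    loglik = data.loglik_at(theta_hat) if not reml else -best.fun
    dfs = _satterthwaite(data, theta_hat, notes)

    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    effects = []
    for j, name in enumerate(names):
        pj = 2.0 * float(stats.t.sf(abs(tvals[j]), dfs[j]))
        r2 = None if name == "intercept" else semipartial_r2_from_t(tvals[j], dfs[j])
        effects.append(FixedEffect(name=name, estimate=float(beta[j]), se=float(se[j]),
                                   t=float(tvals[j]), df=float(dfs[j]), p=pj,
                                   semipartial_r2=r2))

    var_components = {g: float(t) for g, t in zip(groups, taus)}
    return AnalysisResult(
        fixed_effects=effects,
        var_components=var_components,
        var_resid=float(sigma2),
        loglik=float(loglik),
        n_items=data.n,
        n_params=X.shape[1] + k + 1,
        converged=converged,
        singular=singular,
        reml=reml,
        model_label=model_label,
        notes=notes,
        optimizer={"starts": diag, "best_fun": float(best.fun)},
    )
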