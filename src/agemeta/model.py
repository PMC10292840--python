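"""Three-level random-effects meta-analysis with correlated sampling errors.

Model for effect size i (Level 2 estimate) in study j (Level 3 cluster):

    y_ij = x_ij' beta + u_j + w_ij + e_ij

with u_j ~ N(0, tau2_study), w_ij ~ N(0, sigma2_estimate) and sampling
errors e within a study correlated at an assumed rho (default 0.5):
Cov(e_i, e_l) = rho * sqrt(v_i * v_l) for same-study pairs, v_i on the
diagonal. Variance components are estimated by restricted maximum
likelihood; inference on beta uses a CR2-type cluster-robust sandwich
clustered on study with Satterthwaite degrees of freedom, which remains
honest at very small numbers of studies (the two-study regime included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .dataset import CATEGORICAL_LEVELS, MetaDataset

RHO_GRID_DEFAULT = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


class SingularDesignError(ValueError):
    """Moderator design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: within-study error correlation and moderators."""

    rho: float = 0.5
    moderators: tuple[str, ...] = ()
    separate_residual_heterogeneity_by: str | None = None

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError(f"rho must be in [0, 1) (got {self.rho})")
        object.__setattr__(self, "moderators", tuple(self.moderators))


@dataclass
class FitResult:
    """REML fit with model-based and cluster-robust inference."""

    beta: np.ndarray
    coef_names: list[str]
    se_model: np.ndarray
    tau2_study: float
    sigma2_estimate: float
    reml_loglik: float
    k: int
    s: int
    rho: float
    Q: float
    Q_df: int
    Q_p: float
    se_robust: np.ndarray | None = None
    df_robust: np.ndarray | None = None
    ci95_robust: np.ndarray | None = None
    p_robust: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    robust_available: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def pooled_r(self) -> float:
        """Intercept; equals the pooled correlation when no moderators."""
        return float(self.beta[0])

    def ci_robust(self, level: float = 0.95) -> np.ndarray:
        """Robust t confidence intervals, one row per coefficient."""
        if not self.robust_available:
            raise ValueError("robust inference not available for this fit")
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_robust)
        half = tcrit * self.se_robust
        return np.column_stack([self.beta - half, self.beta + half])

    def ci_model(self, level: float = 0.95) -> np.ndarray:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        half = zcrit * self.se_model
        return np.column_stack([self.beta - half, self.beta + half])

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "coef_names": self.coef_names,
            "beta": arr(self.beta),
            "se_model": arr(self.se_model),
            "se_robust": arr(self.se_robust),
            "df_robust": arr(self.df_robust),
            "ci95_robust": arr(self.ci95_robust),
            "p_robust": arr(self.p_robust),
            "tau2_study": self.tau2_study,
            "sigma2_estimate": self.sigma2_estimate,
            "Q": self.Q,
            "Q_df": self.Q_df,
            "Q_p": self.Q_p,
            "k": self.k,
            "s": self.s,
            "rho": self.rho,
            "reml_loglik": self.reml_loglik,
            "robust_available": self.robust_available,
            "warnings": self.warnings,
        }


def build_sampling_covariance(dataset: MetaDataset, rho: float) -> np.ndarray:
    """Block-diagonal (by study) sampling covariance of the observed effects.

    Diagonal = var_r; same-study off-diagonals rho*sqrt(v_i*v_l); zero across
    studies. Symmetric positive definite for rho < 1.
    """
    if not (0 <= rho < 1):
        raise ValueError(f"rho must be in [0, 1) (got {rho})")
    v = dataset.v
    sd = np.sqrt(v)
    same = dataset.study_ids[:, None] == dataset.study_ids[None, :]
    V = rho * same * np.outer(sd, sd)
    np.fill_diagonal(V, v)
    return V


def design_matrix(dataset: MetaDataset, moderators: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + moderator columns; categoricals are treatment-coded.

    Category levels are sorted alphabetically and the first observed level
    is the reference, so the coding is reproducible across runs.
    """
    k = dataset.k
    cols = [np.ones(k)]
    names = ["intercept"]
    for m in moderators:
        if m not in dataset.df.columns:
            raise KeyError(f"moderator column {m!r} not in dataset")
        col = dataset.df[m]
        if m in CATEGORICAL_LEVELS or col.dtype == object:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{m}[{lev}]")
        else:
            x = col.to_numpy(float)
            if np.isnan(x).any():
                raise ValueError(f"moderator {m!r} has missing values")
            cols.append(x)
            names.append(m)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix with moderators {list(moderators)} is rank deficient"
        )
    return X, names


def _study_indicator(dataset: MetaDataset) -> np.ndarray:
    ids = pd.factorize(dataset.study_ids)[0]
    Z = np.zeros((dataset.k, ids.max() + 1))
    Z[np.arange(dataset.k), ids] = 1.0
    return Z


def _restricted_loglik(theta, y, X, V, ZZt):
    """REML log-likelihood (constant dropped) at (tau2, sigma2) = theta."""
    tau2, sig2 = theta
    M = V + tau2 * ZZt + sig2 * np.eye(len(y))
    try:
        c, low = cho_factor(M, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdetM = 2 * np.log(np.diag(c)).sum()
    Minv_X = cho_solve((c, low), X, check_finite=False)
    XtMinvX = X.T @ Minv_X
    sign, logdetXX = np.linalg.slogdet(XtMinvX)
    if sign <= 0:
        return -np.inf, None, None
    beta = np.linalg.solve(XtMinvX, Minv_X.T @ y)
    resid = y - X @ beta
    Minv_r = cho_solve((c, low), resid, check_finite=False)
    ll = -0.5 * (logdetM + logdetXX + resid @ Minv_r)
    return ll, beta, np.linalg.inv(XtMinvX)


def _reml_gradient(theta, y, X, V, ZZt):
    """Analytic gradient of the restricted log-likelihood in (tau2, sigma2).

    dll/dtheta_m = -0.5 * [tr(P A_m) - q' A_m q] with P the REML projection
    and q = M^-1 (y - X beta); A_1 = Z Z', A_2 = I.
    """
    tau2, sig2 = theta
    k = len(y)
    M = V + tau2 * ZZt + sig2 * np.eye(k)
    c, low = cho_factor(M, check_finite=False)
    Minv = cho_solve((c, low), np.eye(k), check_finite=False)
    Minv_X = Minv @ X
    XtMinvX_inv = np.linalg.inv(X.T @ Minv_X)
    P = Minv - Minv_X @ XtMinvX_inv @ Minv_X.T
    q = P @ y
    g_tau = -0.5 * (float(np.sum(P * ZZt)) - float(q @ ZZt @ q))
    g_sig = -0.5 * (float(np.trace(P)) - float(q @ q))
    return np.array([g_tau, g_sig])


def _newton_polish(theta, y, X, V, ZZt, ub, iters: int = 12):
    """Projected Newton steps on the analytic gradient.

    Near the optimum the objective itself is flat to machine precision, so
    line searches stall; root-finding on the gradient localizes the maximum
    to ~1e-11 in the components. Rank-deficient directions (e.g. the
    tau2 + sigma2 ridge with one estimate per study) are handled by the
    pseudo-inverse solve. Steps that reduce the likelihood are rejected.
    """
    theta = np.maximum(np.asarray(theta, float), 0.0)
    ll_best = _restricted_loglik(theta, y, X, V, ZZt)[0]
    for _ in range(iters):
        g = _reml_gradient(theta, y, X, V, ZZt)
        free = (theta > 1e-13) | (g > 0)
        gf = np.where(free, g, 0.0)
        if np.max(np.abs(gf)) < 1e-12:
            break
        h = np.maximum(1e-7 * np.maximum(theta, 1e-4), 1e-10)
        H = np.zeros((2, 2))
        for m in range(2):
            tp = theta.copy()
            tp[m] += h[m]
            H[:, m] = (_reml_gradient(tp, y, X, V, ZZt) - g) / h[m]
        H = (H + H.T) / 2
        Hf = H[np.ix_(free.nonzero()[0], free.nonzero()[0])]
        step = np.zeros(2)
        step[free] = -np.linalg.lstsq(Hf, g[free], rcond=1e-10)[0]
        new = np.clip(theta + step, 0.0, ub)
        ll_new = _restricted_loglik(new, y, X, V, ZZt)[0]
        if not np.isfinite(ll_new) or ll_new < ll_best - 1e-9:
            break
        if np.max(np.abs(new - theta)) < 1e-14:
            theta = new
            break
        theta, ll_best = new, max(ll_best, ll_new)
    return theta


def _mom_start(y, X, V, ZZt) -> tuple[float, float]:
    """DerSimonian-Laird-style method-of-moments total heterogeneity, split."""
    v = np.diag(V)
    w = 1 / v
    Xw = X * w[:, None]
    beta = np.linalg.lstsq(X.T @ Xw, Xw.T @ y, rcond=None)[0]
    resid = y - X @ beta
    q = float(w @ resid**2)
    dfq = len(y) - X.shape[1]
    c = w.sum() - np.trace(np.linalg.solve(X.T @ Xw, Xw.T @ (X * (w**2)[:, None])))
    tot = max(0.0, (q - dfq) / max(c, 1e-12))
    return tot / 2, tot / 2


def fit_reml(dataset: MetaDataset, spec: ModelSpec | None = None,
             robust: bool = True) -> FitResult:
    """Fit the three-level model by REML; optionally add robust inference.

    The two variance components are profiled against beta and maximized
    with multistart bounded optimization (zero start plus a
    method-of-moments start), then polished by Nelder-Mead; boundary
    solutions (a component exactly 0) are admissible.
    """
    spec = spec or ModelSpec()
    y = dataset.y
    X, names = design_matrix(dataset, spec.moderators)
    k, p = X.shape
    if k <= p and k > 1:
        raise ValueError(f"need k > p (k={k}, p={p})")
    warns: list[str] = []

    if k == 1:
        fit = FitResult(
            beta=np.array([float(y[0])]), coef_names=["intercept"],
            se_model=np.array([float(np.sqrt(dataset.v[0]))]),
            tau2_study=0.0, sigma2_estimate=0.0, reml_loglik=0.0,
            k=1, s=1, rho=spec.rho, Q=0.0, Q_df=0, Q_p=1.0,
            warnings=["single estimate: variance components fixed at 0"],
        )
        return fit

    V = build_sampling_covariance(dataset, spec.rho)
    Z = _study_indicator(dataset)
    ZZt = Z @ Z.T

    def neg(theta):
        ll, _, _ = _restricted_loglik(np.maximum(theta, 0.0), y, X, V, ZZt)
        return -ll if np.isfinite(ll) else 1e12

    scale = max(float(np.var(y)), float(np.mean(dataset.v)), 1e-6)
    ub = 20 * scale
    starts = [(1e-8, 1e-8), _mom_start(y, X, V, ZZt), (scale / 2, scale / 2)]
    best = None
    trace = []
    for s0 in starts:
        res = optimize.minimize(
            neg, np.clip(s0, 0, ub), method="L-BFGS-B",
            bounds=[(0.0, ub)] * 2,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        trace.append((s0, res.x, -res.fun))
        if best is None or res.fun < best.fun:
            best = res
    # Nelder-Mead polish handles the boundary and flat ridges cleanly
    res = optimize.minimize(
        neg, best.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 2000},
    )
    theta = np.maximum(res.x if res.fun <= best.fun else best.x, 0.0)
    # analytic-gradient polish pins the optimum far below optimizer noise
    res2 = optimize.minimize(
        lambda th: -_restricted_loglik(np.maximum(th, 0.0), y, X, V, ZZt)[0],
        theta, jac=lambda th: -_reml_gradient(np.maximum(th, 0.0), y, X, V, ZZt),
        method="L-BFGS-B", bounds=[(0.0, ub)] * 2,
        options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 200},
    )
    if np.isfinite(res2.fun) and res2.fun <= neg(theta) + 1e-12:
        theta = np.maximum(res2.x, 0.0)
    theta = _newton_polish(theta, y, X, V, ZZt, ub)
    ll, beta, cov_beta = _restricted_loglik(theta, y, X, V, ZZt)
    if not np.isfinite(ll):
        raise ConvergenceError("REML objective not finite at optimum", trace)
    tau2, sig2 = float(theta[0]), float(theta[1])

    se_model = np.sqrt(np.diag(cov_beta))
    Q, Q_df, Q_p = cochran_q(dataset, spec)

    fit = FitResult(
        beta=beta, coef_names=names, se_model=se_model,
        tau2_study=tau2, sigma2_estimate=sig2, reml_loglik=float(ll),
        k=k, s=dataset.s, rho=spec.rho, Q=Q, Q_df=Q_df, Q_p=Q_p,
        warnings=warns,
    )
    if robust and dataset.s >= 2:
        fit = robust_inference(fit, dataset, spec)
    elif robust:
        fit.warnings.append("single study: cluster-robust inference unavailable")
    return fit


def _sym_sqrt(A: np.ndarray, inv: bool = False, floor: float = 1e-12) -> np.ndarray:
    w, U = np.linalg.eigh((A + A.T) / 2)
    w = np.maximum(w, floor * max(w.max(), 1.0))
    d = w**-0.5 if inv else w**0.5
    return (U * d) @ U.T


def robust_inference(fit: FitResult, dataset: MetaDataset,
                     spec: ModelSpec | None = None) -> FitResult:
    """CR2 cluster-robust (sandwich) inference clustered on study.

    The working covariance is the fitted marginal covariance; cluster
    residuals are inflated by the CR2 adjustment A_j satisfying
    A_j (Phi_j - X_j M X_j') A_j' = Phi_j, and per-coefficient degrees of
    freedom come from a Satterthwaite approximation evaluated under the
    working model. Degrees of freedom are floored at 1; a warning is added
    below 4, where t intervals are very wide (by design, not by accident).
    """
    spec = spec or ModelSpec(rho=fit.rho)
    if dataset.s < 2:
        raise ValueError("cluster-robust inference needs at least 2 studies")
    y = dataset.y
    X, _ = design_matrix(dataset, spec.moderators)
    k, p = X.shape
    V = build_sampling_covariance(dataset, spec.rho)
    Z = _study_indicator(dataset)
    Phi = V + fit.tau2_study * (Z @ Z.T) + fit.sigma2_estimate * np.eye(k)
    W = np.linalg.inv(Phi)
    M = np.linalg.inv(X.T @ W @ X)
    beta = M @ (X.T @ (W @ y))
    e = y - X @ beta

    ids = pd.factorize(dataset.study_ids)[0]
    clusters = [np.where(ids == j)[0] for j in range(ids.max() + 1)]

    meat = np.zeros((p, p))
    # per-cluster pieces reused by the Satterthwaite step
    UWX = []  # A_j' W_j X_j  (n_j x p)
    Phi_half = np.zeros((k, k))
    warns = list(fit.warnings)
    for idx in clusters:
        Phi_j = Phi[np.ix_(idx, idx)]
        X_j = X[idx]
        W_j = W[np.ix_(idx, idx)]
        D_j = Phi_j - X_j @ M @ X_j.T
        C = _sym_sqrt(Phi_j)
        Cinv = np.linalg.inv(C)
        S = Cinv @ D_j @ Cinv.T
        A_j = C @ _sym_sqrt(S, inv=True) @ Cinv
        g = X_j.T @ W_j.T @ A_j @ e[idx]
        meat += np.outer(g, g)
        UWX.append(A_j.T @ W_j @ X_j)
        Phi_half[np.ix_(idx, idx)] = C
    vcov = M @ meat @ M
    vcov = (vcov + vcov.T) / 2
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    # Satterthwaite df per coefficient from the working model
    WXM = W @ X @ M
    df = np.zeros(p)
    for i in range(p):
        G = np.zeros((len(clusters), k))
        for jj, idx in enumerate(clusters):
            q_j = UWX[jj][:, i]  # A_j' W_j X_j e_i contrast
            b = np.zeros(k)
            b[idx] = q_j
            t = b - WXM @ (X.T @ b)
            G[jj] = Phi_half @ t
        GG = G @ G.T
        tr = np.trace(GG)
        tr2 = float((GG * GG).sum())
        df[i] = max(tr**2 / tr2, 1.0) if tr2 > 0 else 1.0
    if (df < 4).any():
        warns.append(
            "robust df < 4 for some coefficients: small-sample inference is unstable"
        )
    tcrit = stats.t.ppf(0.975, df)
    ci = np.column_stack([beta - tcrit * se, beta + tcrit * se])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    return replace(
        fit, beta=beta, se_robust=se, df_robust=df, ci95_robust=ci,
        p_robust=pvals, vcov_robust=vcov, robust_available=True, warnings=warns,
    )


def cochran_q(dataset: MetaDataset, spec: ModelSpec | None = None) -> tuple[float, int, float]:
    """Cochran's Q from the fixed-effects GLS fit under the rho-informed
    sampling covariance; df = k - p, p-value from the chi-square upper tail."""
    spec = spec or ModelSpec()
    y = dataset.y
    X, _ = design_matrix(dataset, spec.moderators)
    k, p = X.shape
    if k <= p:
        return 0.0, 0, 1.0
    V = build_sampling_covariance(dataset, spec.rho)
    W = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ (W @ y))
    resid = y - X @ beta
    Q = float(resid @ W @ resid)
    df = k - p
    return Q, df, float(stats.chi2.sf(Q, df))


def influence_analysis(dataset: MetaDataset, spec: ModelSpec | None = None,
                       threshold: float = 0.05) -> pd.DataFrame:
    """Leave-one-study-out pooled estimates.

    Flags studies whose omission moves the pooled estimate by more than
    ``threshold`` on the correlation scale.
    """
    spec = spec or ModelSpec()
    if dataset.s < 3:
        raise ValueError(f"influence analysis needs >= 3 studies (got {dataset.s})")
    full = fit_reml(dataset, spec)
    rows = []
    for sid in pd.unique(dataset.study_ids):
        sub = dataset.subset(dataset.df["study_id"] != sid)
        f = fit_reml(sub, spec)
        lo, hi = (f.ci95_robust[0] if f.robust_available else f.ci_model()[0])
        rows.append({
            "omitted_study_id": sid,
            "pooled_r": f.pooled_r,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "delta": f.pooled_r - full.pooled_r,
            "flagged": abs(f.pooled_r - full.pooled_r) > threshold,
        })
    return pd.DataFrame(rows)


def subgroup_fit(dataset: MetaDataset, by: str,
                 spec: ModelSpec | None = None) -> dict[str, FitResult]:
    """Independent fit per level of a categorical moderator.

    Each level gets its own variance components (residual heterogeneity is
    allowed to differ between levels, unlike a meta-regression on the same
    factor). Levels with k <= 1 effect sizes are skipped with a warning.
    """
    spec = spec or ModelSpec()
    out: dict[str, FitResult] = {}
    for level in sorted(pd.unique(dataset.df[by].astype(str))):
        sub = dataset.subset(dataset.df[by].astype(str) == level)
        if sub.k <= 1:
            warnings.warn(f"subgroup {by}={level!r} has k={sub.k}; skipped")
            continue
        out[level] = fit_reml(sub, spec)
    return out


def rho_sensitivity(dataset: MetaDataset, spec: ModelSpec | None = None,
                    grid: tuple[float, ...] = RHO_GRID_DEFAULT) -> pd.DataFrame:
    """Pooled estimate and robust CI across the within-study correlation grid."""
    spec = spec or ModelSpec()
    rows = []
    for rho in grid:
        f = fit_reml(dataset, replace(spec, rho=rho))
        lo, hi = (f.ci95_robust[0] if f.robust_available else f.ci_model()[0])
        rows.append({
            "rho": rho, "pooled_r": f.pooled_r, "ci_low": float(lo),
            "ci_high": float(hi), "tau2_study": f.tau2_study,
            "sigma2_estimate": f.sigma2_estimate,
        })
    return pd.DataFrame(rows)


def pair_fit(y1: float, se1: float, y2: float, se2: float,
             rho: float = 0.5) -> FitResult:
    """Convenience: three-level fit of two single-estimate studies.

    Used for worked examples where only two (effect, SE) pairs are known.
    """
    from .dataset import from_dataframe

    df = pd.DataFrame({
        "record_id": ["e1", "e2"], "study_id": ["s1", "s2"],
        "estimate_id": ["e1", "e2"], "preference": ["time", "time"],
        "r": [y1, y2], "var_r": [se1**2, se2**2], "n": [20, 20],
        "year": [1994, 2002], "metric": ["point_biserial", "pearson"],
        "design": ["extreme_group", "continuous"],
        "age_span_decades": [5.0, 5.0], "prop_female": [np.nan, np.nan],
        "incentivized": ["missing", "missing"], "task_type": ["missing", "missing"],
        "domain": ["missing", "missing"], "context": ["missing", "missing"],
        "effort_type": ["missing", "missing"],
        "citations_per_year": [np.nan, np.nan],
    })
    return fit_reml(from_dataframe(df), ModelSpec(rho=rho))
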