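"""Publication-bias diagnostics: Egger-type tests, p-curve, funnel data.

The headline small-study-effect test enters the standard error as a
moderator inside the three-level model (a multilevel PET variant), so the
within-study dependence structure is kept; the classical weighted Egger
regression is also reported for reference. The p-curve battery follows
the standard pp-value/Stouffer construction with the 33%-power flatness
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import MetaDataset
from .model import ModelSpec, fit_reml

ALPHA_SIG = 0.05
#: noncentrality of a two-sided alpha=.05 z test with 33% power
_DELTA_33 = stats.norm.ppf(0.975) + stats.norm.ppf(1 / 3)


@dataclass(frozen=True)
class EggerResult:
    coef_se: float          # multilevel coefficient on sqrt(var_r)
    se: float
    p: float
    df: float
    classical_slope: float  # weighted-regression Egger slope on SE
    classical_se: float
    classical_p: float
    k: int

    def to_dict(self) -> dict:
        return {
            "coef_se": self.coef_se, "se": self.se, "p": self.p, "df": self.df,
            "classical_slope": self.classical_slope,
            "classical_se": self.classical_se, "classical_p": self.classical_p,
            "k": self.k,
        }


@dataclass(frozen=True)
class PCurveResult:
    n_significant: int
    z_rightskew: float | None
    p_rightskew: float | None
    z_flat: float | None
    p_flat: float | None
    available: bool

    def to_dict(self) -> dict:
        return {
            "n_significant": self.n_significant,
            "z_rightskew": self.z_rightskew, "p_rightskew": self.p_rightskew,
            "z_flat": self.z_flat, "p_flat": self.p_flat,
            "available": self.available,
        }


def egger_test(dataset: MetaDataset, spec: ModelSpec | None = None) -> EggerResult:
    """Small-study-effect test: SE as a moderator in the three-level model.

    A nonzero coefficient on sqrt(var_r) signals funnel asymmetry. With
    fewer than 10 effect sizes the test is computed but underpowered; with
    fewer than 3 it is refused, as is a design where all variances are
    equal (the SE column is then collinear with the intercept).
    """
    spec = spec or ModelSpec()
    if dataset.k < 3:
        raise ValueError(f"Egger test needs >= 3 effect sizes (got {dataset.k})")
    se_col = np.sqrt(dataset.v)
    if np.allclose(se_col, se_col[0]):
        raise ValueError(
            "all sampling variances are equal: the SE moderator is collinear "
            "with the intercept and the Egger coefficient is inestimable"
        )
    ds = dataset.subset(slice(None))
    ds.df["sqrt_var_r"] = np.sqrt(ds.df["var_r"].to_numpy(float))
    fit = fit_reml(ds, replace(spec, moderators=("sqrt_var_r",)))
    i = fit.coef_names.index("sqrt_var_r")
    if fit.robust_available:
        coef, se, p = fit.beta[i], fit.se_robust[i], fit.p_robust[i]
        df = fit.df_robust[i]
    else:
        coef, se = fit.beta[i], fit.se_model[i]
        p = 2 * stats.norm.sf(abs(coef / se))
        df = np.inf

    # classical Egger: WLS of r on SE with inverse-variance weights
    X = sm.add_constant(se_col)
    wls = sm.WLS(dataset.y, X, weights=1 / dataset.v).fit()
    return EggerResult(
        coef_se=float(coef), se=float(se), p=float(p), df=float(df),
        classical_slope=float(wls.params[1]), classical_se=float(wls.bse[1]),
        classical_p=float(wls.pvalues[1]), k=dataset.k,
    )


def p_curve(dataset: MetaDataset) -> PCurveResult:
    """Right-skew and flatness tests on the significant p-values.

    Each effect gets a two-sided p from z = r / sqrt(var_r); effects with
    p < .05 enter with pp = p/.05 (uniform under the null given
    significance). Right-skew: Stouffer combination of Phi^-1(pp); a very
    negative z (small pp-values) indicates evidential value, so
    p_rightskew is the lower normal tail. Flatness: pp-values recomputed
    under a 33%-power alternative; a large positive Stouffer z (pp33 near
    1) indicates a curve flatter than 33% power, so p_flat is the upper
    tail.
    """
    z_obs = np.abs(dataset.y) / np.sqrt(dataset.v)
    p_two = 2 * stats.norm.sf(z_obs)
    sig = p_two < ALPHA_SIG
    m = int(sig.sum())
    if m == 0:
        return PCurveResult(0, None, None, None, None, False)
    pp = p_two[sig] / ALPHA_SIG
    pp = np.clip(pp, 1e-12, 1 - 1e-12)
    z_rs = float(stats.norm.ppf(pp).sum() / np.sqrt(m))
    p_rs = float(stats.norm.cdf(z_rs))

    zcrit = stats.norm.ppf(1 - ALPHA_SIG / 2)
    # P(Z > z | significant) under the 33%-power noncentral alternative
    pow33 = stats.norm.cdf(_DELTA_33 - zcrit)
    pp33 = stats.norm.cdf(_DELTA_33 - z_obs[sig]) / pow33
    pp33 = np.clip(pp33, 1e-12, 1 - 1e-12)
    z_flat = float(stats.norm.ppf(pp33).sum() / np.sqrt(m))
    p_flat = float(stats.norm.sf(z_flat))
    return PCurveResult(m, z_rs, p_rs, z_flat, p_flat, True)


def funnel_data(dataset: MetaDataset, spec: ModelSpec | None = None,
                n_contour: int = 50) -> dict:
    """Per-record (r, se) points with the pooled centerline and pseudo-CI
    contours (center +- 1.96*se over an SE grid). Data only, no plotting."""
    spec = spec or ModelSpec()
    points = pd.DataFrame({
        "record_id": dataset.df["record_id"],
        "r": dataset.y,
        "se": np.sqrt(dataset.v),
    })
    if dataset.k == 1:
        center = float(dataset.y[0])
    else:
        center = fit_reml(dataset, spec, robust=False).pooled_r
    se_max = float(points["se"].max()) * 1.05
    se_grid = np.linspace(0, se_max, n_contour)
    zc = stats.norm.ppf(0.975)
    contours = pd.DataFrame({
        "se": se_grid,
        "lower": center - zc * se_grid,
        "upper": center + zc * se_grid,
    })
    return {"points": points, "center": center, "contours": contours}
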