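"""Equivalence (TOST) testing of the pooled effect against +-SESOI bounds.

The smallest effect size of interest defaults to r = 0.1, a conventional
"small" correlation typical of individual-differences research. The effect
is declared equivalent to zero when both one-sided tests against the
bounds reject at alpha, which is the same thing as the 90% confidence
interval lying strictly inside (-bound, +bound).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import FitResult


@dataclass(frozen=True)
class EquivalenceResult:
    bound: float
    alpha: float
    beta: float
    se: float
    z_lower: float
    z_upper: float
    p_lower: float
    p_upper: float
    verdict: str  # equivalent | not_equivalent | inconclusive
    distinguishable_from_lower: bool
    distinguishable_from_upper: bool
    # conservative t-reference variants (same statistics, t(df_robust) tails)
    p_lower_t: float | None = None
    p_upper_t: float | None = None

    @property
    def z(self) -> float:
        """The binding (smaller) of the two one-sided statistics."""
        return min(self.z_lower, self.z_upper)

    def to_dict(self) -> dict:
        return {
            "bound": self.bound, "alpha": self.alpha, "beta": self.beta,
            "se": self.se, "z_lower": self.z_lower, "z_upper": self.z_upper,
            "p_lower": self.p_lower, "p_upper": self.p_upper,
            "verdict": self.verdict,
            "distinguishable_from_lower": self.distinguishable_from_lower,
            "distinguishable_from_upper": self.distinguishable_from_upper,
            "p_lower_t": self.p_lower_t, "p_upper_t": self.p_upper_t,
        }


def equivalence_test(fit: FitResult, bound: float = 0.1,
                     alpha: float = 0.05) -> EquivalenceResult:
    """Two one-sided z tests of the pooled effect against -bound and +bound.

    Uses the cluster-robust SE of the intercept. The normal reference is
    primary (matching the usual reporting of an equivalence z); t-referenced
    p-values with the robust Satterthwaite df are also returned.

    Verdict: ``equivalent`` when both one-sided tests reject at alpha;
    ``not_equivalent`` when the (1-2*alpha) CI lies entirely outside the
    bounds (the effect is demonstrably at least bound-sized); otherwise
    ``inconclusive``.
    """
    if bound <= 0:
        raise ValueError(f"equivalence bound must be > 0 (got {bound})")
    if not fit.robust_available:
        raise ValueError("equivalence test requires robust inference on the fit")
    beta = float(fit.beta[0])
    se = float(fit.se_robust[0])
    z_lower = (beta + bound) / se  # H0: beta <= -bound, reject for large z
    z_upper = (bound - beta) / se  # H0: beta >= +bound, reject for large z
    p_lower = float(stats.norm.sf(z_lower))
    p_upper = float(stats.norm.sf(z_upper))
    df = float(fit.df_robust[0])
    p_lower_t = float(stats.t.sf(z_lower, df))
    p_upper_t = float(stats.t.sf(z_upper, df))

    if p_lower < alpha and p_upper < alpha:
        verdict = "equivalent"
    else:
        zcrit = stats.norm.ppf(1 - alpha)
        lo, hi = beta - zcrit * se, beta + zcrit * se
        verdict = "not_equivalent" if (lo > bound or hi < -bound) else "inconclusive"

    # distinguishability from each bound: two-sided z test against the bound
    p_vs_lower = 2 * stats.norm.sf(abs(z_lower))
    p_vs_upper = 2 * stats.norm.sf(abs(z_upper))
    return EquivalenceResult(
        bound=bound, alpha=alpha, beta=beta, se=se,
        z_lower=float(z_lower), z_upper=float(z_upper),
        p_lower=p_lower, p_upper=p_upper, verdict=verdict,
        distinguishable_from_lower=bool(p_vs_lower < alpha),
        distinguishable_from_upper=bool(p_vs_upper < alpha),
        p_lower_t=p_lower_t, p_upper_t=p_upper_t,
    )


def interval_plot_data(fit: FitResult, bound: float = 0.1) -> dict:
    """Point estimate with 90%/95% robust CIs and the shaded bounds,
    ready for an equivalence-style interval plot."""
    ci95 = fit.ci_robust(0.95)[0]
    ci90 = fit.ci_robust(0.90)[0]
    return {
        "estimate": float(fit.beta[0]),
        "ci90": [float(ci90[0]), float(ci90[1])],
        "ci95": [float(ci95[0]), float(ci95[1])],
        "bounds": [-bound, bound],
    }
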