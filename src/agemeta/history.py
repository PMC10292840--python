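"""Cumulative meta-analysis and historical-trend analyses.

The cumulative trace refits the three-level model as the literature
accrues, either year by year (several studies published in the same year
enter together) or study by study (studies ordered by publication year,
ties broken by study id). Trend analyses regress effect sizes on decades
since publication (meta-regression), log sample size on year (OLS), and
citations per year on log sample size and effect magnitude (OLS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import MetaDataset
from .model import FitResult, ModelSpec, fit_reml


@dataclass
class CumulativeTrace:
    """Ordered pooled estimates with CIs as evidence accumulates."""

    order: str  # by_year | by_study
    steps: pd.DataFrame  # cutoff, pooled_r, ci_low, ci_high, k, s, robust
    final_fit: FitResult

    def to_csv(self, path=None):
        return self.steps.to_csv(path, index=False)


@dataclass(frozen=True)
class ProteusResult:
    """First-vs-rest contrast for an extreme early finding."""

    z: float
    p: float
    first_study_id: str
    first_effect: float
    first_variance: float
    rest_mean_effect: float
    rest_mean_variance: float

    def to_dict(self) -> dict:
        return {
            "z": self.z, "p": self.p, "first_study_id": self.first_study_id,
            "first_effect": self.first_effect,
            "first_variance": self.first_variance,
            "rest_mean_effect": self.rest_mean_effect,
            "rest_mean_variance": self.rest_mean_variance,
        }


def _study_order(dataset: MetaDataset) -> list[str]:
    first_year = dataset.df.groupby("study_id")["year"].min()
    return sorted(first_year.index, key=lambda sid: (first_year[sid], sid))


def cumulative_meta(dataset: MetaDataset, order: str = "by_year",
                    spec: ModelSpec | None = None) -> CumulativeTrace:
    """Refit the model at each cutoff as effect sizes accrue chronologically.

    ``by_year``: cutoffs are the distinct publication years, all effect
    sizes with year <= cutoff included. ``by_study``: one study added at a
    time in (year, study_id) order; the cutoff is the study index. Steps
    with a single study report the model-based CI with robust inference
    marked unavailable. Failures at intermediate cutoffs are recorded in
    the step table rather than raised.
    """
    spec = spec or ModelSpec()
    if order not in ("by_year", "by_study"):
        raise ValueError(f"order must be by_year or by_study (got {order!r})")
    rows = []
    if order == "by_year":
        cutoffs = sorted(dataset.df["year"].unique())
        subsets = [(int(cy), dataset.subset(dataset.df["year"] <= cy)) for cy in cutoffs]
    else:
        sids = _study_order(dataset)
        subsets = []
        for i in range(1, len(sids) + 1):
            mask = dataset.df["study_id"].isin(sids[:i])
            subsets.append((i, dataset.subset(mask)))
    fit = None
    for cutoff, sub in subsets:
        try:
            fit = fit_reml(sub, spec)
            if fit.robust_available:
                lo, hi = fit.ci95_robust[0]
            else:
                lo, hi = fit.ci_model()[0]
            rows.append({
                "cutoff": cutoff, "pooled_r": fit.pooled_r,
                "ci_low": float(lo), "ci_high": float(hi),
                "k": fit.k, "s": fit.s,
                "robust": fit.robust_available, "error": "",
            })
        except Exception as exc:  # record, do not abort the trace
            rows.append({
                "cutoff": cutoff, "pooled_r": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "k": sub.k, "s": sub.s,
                "robust": False, "error": str(exc),
            })
    return CumulativeTrace(order=order, steps=pd.DataFrame(rows), final_fit=fit)


def proteus_test(dataset: MetaDataset) -> ProteusResult:
    """First-study-vs-rest z test for the Proteus phenomenon.

    Studies contributing several effect sizes enter through their
    unweighted within-study mean effect and mean sampling variance. The
    statistic is signed rest-minus-first, so an extreme negative first
    study yields a positive z:

        z = (m_rest - y_first) / sqrt(v_first + vbar_rest)
    """
    if dataset.s < 3:
        raise ValueError(f"Proteus test needs >= 3 studies (got {dataset.s})")
    agg = dataset.df.groupby("study_id").agg(
        r=("r", "mean"), v=("var_r", "mean"), year=("year", "min")
    )
    first_sid = sorted(agg.index, key=lambda sid: (agg.loc[sid, "year"], sid))[0]
    y_first = float(agg.loc[first_sid, "r"])
    v_first = float(agg.loc[first_sid, "v"])
    rest = agg.drop(index=first_sid)
    m_rest = float(rest["r"].mean())
    v_rest = float(rest["v"].mean())
    z = (m_rest - y_first) / np.sqrt(v_first + v_rest)
    p = float(2 * stats.norm.sf(abs(z)))
    return ProteusResult(
        z=float(z), p=p, first_study_id=first_sid,
        first_effect=y_first, first_variance=v_first,
        rest_mean_effect=m_rest, rest_mean_variance=v_rest,
    )


def trend_decades(dataset: MetaDataset, reference_year: int = 2022,
                  spec: ModelSpec | None = None) -> FitResult:
    """Meta-regression of effect sizes on decades since publication.

    The moderator is (reference_year - year) / 10, so the slope is the
    change in the pooled correlation per decade of article age.
    """
    spec = spec or ModelSpec()
    if dataset.df["year"].nunique() < 2:
        raise ValueError("trend regression needs >= 2 distinct publication years")
    ds = dataset.subset(slice(None))
    ds.df["decades_since_pub"] = (reference_year - ds.df["year"]) / 10.0
    return fit_reml(ds, replace(spec, moderators=("decades_since_pub",)))


def sample_size_trend(dataset: MetaDataset) -> dict:
    """OLS of log study sample size on publication year (one n per study)."""
    per_study = dataset.df.groupby("study_id").agg(
        n=("n", "max"), year=("year", "min")
    )
    if len(per_study) < 3:
        raise ValueError("need >= 3 studies with sample size and year")
    if per_study["year"].nunique() < 2:
        raise ValueError("all studies share one publication year; trend undefined")
    X = sm.add_constant(per_study["year"].to_numpy(float))
    res = sm.OLS(np.log(per_study["n"].to_numpy(float)), X).fit()
    return {
        "slope": float(res.params[1]), "se": float(res.bse[1]),
        "p": float(res.pvalues[1]), "intercept": float(res.params[0]),
        "n_studies": int(len(per_study)),
    }


def citation_trend(dataset: MetaDataset) -> pd.DataFrame:
    """Study-level OLS of citations/year on log sample size and |r|.

    Uses each study's largest record n, its mean |r|, and its (first
    non-missing) citations-per-year value.
    """
    per_study = dataset.df.groupby("study_id").agg(
        n=("n", "max"),
        abs_r=("r", lambda x: float(np.mean(np.abs(x)))),
        citations=("citations_per_year", "first"),
    ).dropna(subset=["citations"])
    if len(per_study) < 5:
        raise ValueError(
            f"citation regression needs >= 5 studies with citations "
            f"(got {len(per_study)})"
        )
    X = sm.add_constant(
        np.column_stack([np.log(per_study["n"].to_numpy(float)),
                         per_study["abs_r"].to_numpy(float)])
    )
    res = sm.OLS(per_study["citations"].to_numpy(float), X).fit()
    return pd.DataFrame({
        "term": ["intercept", "log_n", "abs_r"],
        "coef": res.params, "se": res.bse, "p": res.pvalues,
    })
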