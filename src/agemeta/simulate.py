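"""Synthetic effect-size literatures with three-level structure.

The generator draws study effects mu + trend + N(0, tau2_study), adds
estimate-level deviations N(0, sigma2_estimate), and observes each
estimate with correlated within-study sampling error on the raw
correlation scale (variance (1 - r^2)^2 / (n - 1), within-study
correlation rho). Optional one-sided censoring of nonsignificant negative
effects and a planted extreme first study make publication-bias and
Proteus scenarios reproducible. Every study has its own deterministic
substream, so enlarging a simulated literature never perturbs the studies
already in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import MetaDataset, from_dataframe

_DOMAINS = ("gain", "loss", "mixed")
_TASKS = ("description", "experience")
_CONTEXTS = ("lab", "online")
_INCENT = ("hypothetical", "incentivized")


class ConfigError(ValueError):
    """Invalid simulation configuration; lists the offending fields."""


@dataclass(frozen=True)
class SimConfig:
    """Data-generating parameters for one synthetic literature."""

    seed: int = 0
    preference: str = "risk"
    s: int = 20
    estimates_per_study: int | tuple[int, int] = 3
    k_total: int | None = None  # exact total; overrides estimates_per_study
    mu: float = 0.0
    tau2_study: float = 0.02
    sigma2_estimate: float = 0.01
    rho: float = 0.5
    n_range: tuple[int, int] = (30, 300)
    year_range: tuple[int, int] = (1994, 2022)
    trend_per_decade: float = 0.0
    censor_nonsignificant: float = 0.0
    proteus_first_study: tuple[float, float] | None = None  # (effect, se)
    moderator_effects: dict = field(default_factory=dict)

    def validate(self) -> None:
        bad = []
        if self.s < 1:
            bad.append(f"s={self.s} (need >= 1)")
        if self.tau2_study < 0:
            bad.append(f"tau2_study={self.tau2_study} (need >= 0)")
        if self.sigma2_estimate < 0:
            bad.append(f"sigma2_estimate={self.sigma2_estimate} (need >= 0)")
        if not (0 <= self.rho < 1):
            bad.append(f"rho={self.rho} (need [0,1))")
        if not (0 <= self.censor_nonsignificant <= 1):
            bad.append(f"censor_nonsignificant={self.censor_nonsignificant}")
        if not (-1 < self.mu < 1):
            bad.append(f"mu={self.mu} (need (-1,1))")
        if self.n_range[0] < 3 or self.n_range[0] > self.n_range[1]:
            bad.append(f"n_range={self.n_range}")
        if self.year_range[0] > self.year_range[1]:
            bad.append(f"year_range={self.year_range}")
        if bad:
            raise ConfigError("invalid SimConfig fields: " + "; ".join(bad))


def _counts(config: SimConfig) -> list[int]:
    """Estimates per study; k_total is split as evenly as possible.

    A planted first study always contributes exactly one record, so the
    remaining total is spread over the other studies.
    """
    if config.k_total is not None:
        if config.proteus_first_study is not None:
            base, rem = divmod(config.k_total - 1, config.s - 1)
            if base < 1:
                raise ConfigError("k_total smaller than study count")
            return [1] + [base + (1 if j < rem else 0) for j in range(config.s - 1)]
        base, rem = divmod(config.k_total, config.s)
        if base < 1:
            raise ConfigError("k_total smaller than study count")
        return [base + (1 if j < rem else 0) for j in range(config.s)]
    eps = config.estimates_per_study
    if isinstance(eps, int):
        return [eps] * config.s
    lo, hi = eps
    out = []
    for j in range(config.s):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(9000 + j,))
        )
        out.append(int(rng.integers(lo, hi + 1)))
    return out


def _truncated_effects(rng, theta, n, rho, max_tries=200):
    """Observed correlations: MVN sampling error, resampled until |r| < 1."""
    m = len(theta)
    sd = (1 - np.minimum(theta**2, 0.999)) / np.sqrt(n - 1)
    C = np.full((m, m), rho) * np.outer(sd, sd)
    np.fill_diagonal(C, sd**2)
    L = np.linalg.cholesky(C + 1e-14 * np.eye(m))
    for _ in range(max_tries):
        r = theta + L @ rng.standard_normal(m)
        if np.all(np.abs(r) < 0.999):
            return r, sd**2
    return np.clip(r, -0.99, 0.99), sd**2


def generate(config: SimConfig) -> MetaDataset:
    """Generate one validated synthetic literature."""
    config.validate()
    counts = _counts(config)
    y0, y1 = config.year_range
    rows = []
    for j in range(config.s):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(j,)))
        sid = f"study_{j:03d}"
        if config.proteus_first_study is not None and j == 0:
            eff, se = config.proteus_first_study
            n = max(3, int(round((1 - eff**2) ** 2 / se**2 + 1)))
            rows.append(_row(config, rng, sid, 0, eff, se**2, n, y0))
            continue
        lo = y0 + 1 if config.proteus_first_study is not None else y0
        year = int(rng.integers(lo, y1 + 1))
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        theta_s = (
            config.mu
            + config.trend_per_decade * (year - y1) / 10.0
            + np.sqrt(config.tau2_study) * rng.standard_normal()
        )
        m = counts[j]
        theta = theta_s + np.sqrt(config.sigma2_estimate) * rng.standard_normal(m)
        # moderator levels drawn before effects so shifts are reproducible
        mods = [_draw_moderators(config, rng) for _ in range(m)]
        for i, md in enumerate(mods):
            for col, shifts in config.moderator_effects.items():
                theta[i] += shifts.get(md[col], 0.0)
        theta = np.clip(theta, -0.98, 0.98)
        r_obs, var_r = _truncated_effects(rng, theta, n, config.rho)
        for i in range(m):
            if config.censor_nonsignificant > 0:
                z = r_obs[i] / np.sqrt(var_r[i])
                nonsig_negative = r_obs[i] < 0 and abs(z) < 1.959963984540054
                if nonsig_negative and rng.random() < config.censor_nonsignificant:
                    continue
            rows.append(
                _row(config, rng, sid, i, float(r_obs[i]), float(var_r[i]),
                     n, year, mods[i])
            )
    if not rows:
        raise ConfigError("censoring removed every record; relax the configuration")
    df = pd.DataFrame(rows)
    return from_dataframe(df, config.preference)


def _draw_moderators(config: SimConfig, rng) -> dict:
    md = {
        "design": rng.choice(("continuous", "extreme_group")),
        "incentivized": rng.choice(_INCENT),
        "task_type": rng.choice(_TASKS),
        "domain": rng.choice(_DOMAINS),
        "context": rng.choice(_CONTEXTS),
        "effort_type": (
            rng.choice(("cognitive", "physical"))
            if config.preference == "effort" else "missing"
        ),
    }
    md["metric"] = "point_biserial" if md["design"] == "extreme_group" else "pearson"
    return md


def _row(config, rng, sid, i, r, var_r, n, year, mods=None):
    mods = mods or _draw_moderators(config, rng)
    return {
        "record_id": f"{sid}_e{i:02d}",
        "study_id": sid,
        "estimate_id": f"{sid}_e{i:02d}",
        "preference": config.preference,
        "r": round(r, 10),
        "var_r": round(var_r, 12),
        "n": n,
        "year": year,
        "metric": mods["metric"],
        "design": mods["design"],
        "age_span_decades": round(float(rng.uniform(3.0, 6.0)), 2),
        "prop_female": round(float(rng.uniform(0.3, 0.7)), 3),
        "incentivized": mods["incentivized"],
        "task_type": mods["task_type"],
        "domain": mods["domain"],
        "context": mods["context"],
        "effort_type": mods["effort_type"],
        "citations_per_year": round(float(rng.lognormal(1.0, 0.8)), 2),
    }


def scenario_library() -> dict[str, SimConfig]:
    """Named presets shaped like the four preference literatures.

    Counts (studies s, effect sizes k) mirror the four real literatures:
    risk s=62/k=193, time s=54/k=125, social s=15/k=28, effort s=7/k=23.
    The time preset plants the extreme 1994 first study (r=-0.72, SE 0.22)
    so Proteus-style scenarios are available off the shelf. Each preset
    has a ``*_null`` (mu = 0) variant and the base presets carry small
    pooled effects of the sign seen in each literature.
    """
    base = dict(tau2_study=0.02, sigma2_estimate=0.01, rho=0.5)
    presets = {
        "risk_like": SimConfig(
            preference="risk", s=62, k_total=193, mu=-0.02,
            n_range=(20, 2000), year_range=(1994, 2022), **base,
        ),
        "time_like": SimConfig(
            preference="time", s=54, k_total=125, mu=-0.04,
            n_range=(20, 5000), year_range=(1994, 2022),
            proteus_first_study=(-0.72, 0.22), **base,
        ),
        "social_like": SimConfig(
            preference="social", s=15, k_total=28, mu=0.11,
            n_range=(20, 500), year_range=(2002, 2022), **base,
        ),
        "effort_like": SimConfig(
            preference="effort", s=7, k_total=23, mu=0.24,
            n_range=(15, 120), year_range=(2016, 2022), **base,
        ),
    }
    for name in list(presets):
        presets[f"{name}_null"] = replace(
            presets[name], mu=0.0, proteus_first_study=None
        )
        presets[f"{name}_small"] = replace(
            presets[name], mu=0.1, proteus_first_study=None
        )
    return presets
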