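"""End-to-end per-preference analysis: one call, one report bundle.

The bundle directory contains the main fit, rho-sensitivity table,
equivalence test, moderator meta-regressions, subgroup fits, influence
table, cumulative traces (year- and study-wise), Proteus test, trend
regressions, bias diagnostics, funnel table, and a machine-readable
manifest (dataset hash, configuration, package version, per-stage
status). Independent stages keep running when one fails; the failure is
recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bias import egger_test, funnel_data, p_curve
from .dataset import MetaDataset, load_dataset
from .equivalence import equivalence_test, interval_plot_data
from .history import citation_trend, cumulative_meta, proteus_test, sample_size_trend, trend_decades
from .model import (
    ModelSpec,
    RHO_GRID_DEFAULT,
    fit_reml,
    influence_analysis,
    rho_sensitivity,
    subgroup_fit,
)

logger = logging.getLogger("agemeta")

DEFAULT_MODERATORS = (
    "age_span_decades", "prop_female", "metric", "design",
    "incentivized", "domain", "task_type", "context",
)


@dataclass
class PipelineConfig:
    """Defaults reproduce the primary specification: rho = 0.5,
    equivalence bound r = |0.1|, alpha = 5%."""

    input: str | None = None
    preference: str = "risk"
    rho: float = 0.5
    rho_grid: tuple[float, ...] = RHO_GRID_DEFAULT
    equivalence_bound: float = 0.1
    alpha: float = 0.05
    moderators: tuple[str, ...] = ()
    subgroup_columns: tuple[str, ...] = ()
    reference_year: int = 2022
    outdir: str = "results/bundle"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("rho_grid", "moderators", "subgroup_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("rho_grid", "moderators", "subgroup_columns"):
            d[key] = list(d[key])
        return d


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_full_analysis(config: PipelineConfig,
                      dataset: MetaDataset | None = None) -> dict:
    """Run every stage on one dataset and write the report bundle.

    Returns the manifest; ``manifest["failed_stages"]`` is empty on full
    success.
    """
    logging.basicConfig(level=config.log_level)
    if dataset is None:
        dataset = load_dataset(config.input, config.preference)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = ModelSpec(rho=config.rho)
    moderators = config.moderators or tuple(
        m for m in DEFAULT_MODERATORS if dataset.df[m].nunique() > 1
    )
    subgroups = config.subgroup_columns or tuple(
        c for c in ("domain", "task_type") if dataset.df[c].nunique() > 1
    )

    stages: dict[str, str] = {}
    artifacts: list[str] = []
    main_fit = None

    def stage(name, fn, filename, writer):
        nonlocal main_fit
        try:
            result = fn()
            writer(out / filename, result)
            artifacts.append(filename)
            stages[name] = "ok"
            logger.info("stage %s ok (k=%d, s=%d) -> %s",
                        name, dataset.k, dataset.s, filename)
            return result
        except Exception as exc:
            stages[name] = f"failed: {exc}"
            logger.warning("stage %s failed: %s", name, exc)
            return None

    main_fit = stage(
        "main_fit", lambda: fit_reml(dataset, spec), "main_fit.json",
        lambda p, r: _dump_json(p, r.to_dict()),
    )
    stage(
        "rho_sensitivity",
        lambda: rho_sensitivity(dataset, spec, config.rho_grid),
        "rho_sensitivity.csv", lambda p, r: r.to_csv(p, index=False),
    )
    stage(
        "equivalence",
        lambda: {
            **equivalence_test(main_fit, config.equivalence_bound, config.alpha).to_dict(),
            "plot": interval_plot_data(main_fit, config.equivalence_bound),
        },
        "equivalence.json", _dump_json,
    )
    stage(
        "moderators",
        lambda: {
            m: fit_reml(dataset, ModelSpec(rho=config.rho, moderators=(m,))).to_dict()
            for m in moderators
        },
        "moderators.json", _dump_json,
    )
    stage(
        "subgroups",
        lambda: {
            col: {lev: f.to_dict() for lev, f in subgroup_fit(dataset, col, spec).items()}
            for col in subgroups
        },
        "subgroups.json", _dump_json,
    )
    stage(
        "influence", lambda: influence_analysis(dataset, spec),
        "influence.csv", lambda p, r: r.to_csv(p, index=False),
    )
    stage(
        "cumulative_year", lambda: cumulative_meta(dataset, "by_year", spec),
        "cumulative_year.csv", lambda p, r: r.steps.to_csv(p, index=False),
    )
    stage(
        "cumulative_study", lambda: cumulative_meta(dataset, "by_study", spec),
        "cumulative_study.csv", lambda p, r: r.steps.to_csv(p, index=False),
    )
    stage(
        "proteus", lambda: proteus_test(dataset).to_dict(),
        "proteus.json", _dump_json,
    )
    stage(
        "trends",
        lambda: {
            "decades_meta_regression": trend_decades(
                dataset, config.reference_year, spec
            ).to_dict(),
            "sample_size": sample_size_trend(dataset),
            "citations": citation_trend(dataset).to_dict(orient="records"),
        },
        "trends.json", _dump_json,
    )
    stage(
        "bias",
        lambda: {
            "egger": egger_test(dataset, spec).to_dict(),
            "p_curve": p_curve(dataset).to_dict(),
        },
        "bias.json", _dump_json,
    )
    stage(
        "funnel", lambda: funnel_data(dataset, spec),
        "funnel.csv", lambda p, r: r["points"].assign(center=r["center"]).to_csv(p, index=False),
    )

    manifest = {
        "version": __version__,
        "dataset_sha256": dataset.sha256(),
        "preference": dataset.preference,
        "k": dataset.k,
        "s": dataset.s,
        "n_total": dataset.n_total,
        "config": config.to_dict(),
        "artifacts": artifacts,
        "stages": stages,
        "failed_stages": [n for n, st in stages.items() if st != "ok"],
    }
    _dump_json(out / "manifest.json", manifest)
    return manifest
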