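"""One reproducible run: simulate/read -> process -> summarize -> model.

A single :class:`RunConfig` drives everything; stage outputs are plain CSV
so any stage can be re-entered independently, and a JSON manifest records
the config hash, seed, row counts and output checksums.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .datamodel import ConfigurationError
from .models import (
    ModelSpec,
    fit_activity_microclimate_glmm,
    fit_binomial_glmm,
    fit_cell_means,
    fit_lmm,
    tukey_contrasts,
)
from .processing import ProcessingParams, process_records
from .seasons import SEASONS, SeasonRule
from .simulate import SimConfig, simulate_campaign
from .summaries import (
    DEFAULT_LIGHT_THRESHOLD,
    proportion_active_days,
    summarize_campaign,
)

log = logging.getLogger("crustpam")

__all__ = ["RunConfig", "run_pipeline", "report_summary_tables"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    #: Monitoring CSV to analyse; None simulates a campaign instead.
    input_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    season_rule: SeasonRule = field(default_factory=SeasonRule)
    light_threshold: float = DEFAULT_LIGHT_THRESHOLD
    par_variant: str = "qualified"
    activity_day_cutoff: float = 50.0
    #: Fit the treatment x season mixed models (activity GLMMs, climate and
    #: efficiency LMMs) with Tukey contrasts.
    fit_models: bool = True
    #: Fit the 12 per-season/period activity ~ microclimate GLMMs.
    fit_climate_models: bool = True
    out_dir: str = "results/run"
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            for key in ("start_date", "end_date"):
                if key in sim and isinstance(sim[key], str):
                    sim[key] = dt.date.fromisoformat(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        if "processing" in kwargs:
            kwargs["processing"] = ProcessingParams(**kwargs["processing"])
        if "season_rule" in kwargs:
            windows = tuple(
                (tuple(w[0]), tuple(w[1]), w[2]) for w in kwargs["season_rule"]
            )
            kwargs["season_rule"] = SeasonRule(windows=windows)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (dt.date, dt.datetime)):
                return obj.isoformat()
            return str(obj)

        fields = dataclasses.asdict(self)
        # where outputs go and how loudly we log do not affect the results
        fields.pop("out_dir", None)
        fields.pop("log_level", None)
        payload = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim if config.seed is None else config.sim.with_(seed=config.seed)

    if config.input_csv is not None:
        records = _stage("read")(io.read_monitoring_csv)(config.input_csv)
        truth = None
    else:
        records, truth = _stage("simulate")(simulate_campaign)(
            sim, season_rule=config.season_rule, return_truth=True
        )
        io.write_monitoring_csv(records, out / "monitoring.csv")
        io.write_table_csv(truth, out / "truth.csv")
    log.info("input: %d records from %d sensors", len(records), records["sensor_id"].nunique())

    processed = _stage("process")(process_records)(records, config.processing)
    io.write_table_csv(processed, out / "processed.csv")

    summaries = _stage("summarize")(summarize_campaign)(
        processed,
        rule=config.season_rule,
        light_threshold=config.light_threshold,
        par_variant=config.par_variant,
    )
    io.write_table_csv(summaries, out / "daily_summaries.csv")
    proportions = proportion_active_days(
        summaries[summaries["period"] == "diurnal"], cutoff=config.activity_day_cutoff
    )
    io.write_table_csv(proportions, out / "proportion_active_days.csv")

    model_results: dict[str, object] = {}
    if config.fit_models:
        model_results = _stage("model")(_fit_standard_models)(
            summaries, out, fit_climate=config.fit_climate_models
        )

    report = _stage("report")(report_summary_tables)(summaries, model_results)
    io.write_table_csv(report, out / "season_treatment_report.csv")

    by_period = processed.groupby("period").size().to_dict()
    manifest = {
        "config_hash": config.config_hash(),
        "seed": sim.seed,
        "n_input_records": int(len(records)),
        "n_processed_records": int(len(processed)),
        "n_records_diurnal": int(by_period.get("diurnal", 0)),
        "n_records_nocturnal": int(by_period.get("nocturnal", 0)),
        "n_summaries": int(len(summaries)),
        "n_sensor_days": int(summaries.groupby(["sensor_id", "date"]).ngroups),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("manifest: %s", manifest)
    return manifest


def _fit_standard_models(summaries, out: Path, *, fit_climate: bool) -> dict:
    """The treatment x season inference layer; writes one CSV per model."""
    results: dict[str, object] = {}
    coef_rows, contrast_rows = [], []

    jobs: list[tuple[str, ModelSpec]] = []
    for period in ("diurnal", "nocturnal"):
        jobs.append(
            (
                f"activity_{period}",
                ModelSpec(("n_active", "n_records"), "binomial",
                          scope={"period": period}),
            )
        )
        jobs.append(
            (
                f"efficiency_{period}",
                ModelSpec("mean_efficiency", "gaussian", scope={"period": period}),
            )
        )
        for var in ("mean_temperature", "mean_moisture"):
            jobs.append(
                (f"{var.removeprefix('mean_')}_{period}",
                 ModelSpec(var, "gaussian", scope={"period": period}))
            )
    jobs.append(
        (
            "activity_par_diurnal",
            ModelSpec(("n_active_par_ge_threshold", "n_par_ge_threshold"),
                      "binomial", scope={"period": "diurnal"}),
        )
    )

    for name, spec in jobs:
        result, cells = fit_cell_means(summaries, spec)
        tukey_contrasts(result, cells)
        results[name] = result
        for _, row in result.coefficients.iterrows():
            coef_rows.append({"model": name, **row})
        for _, row in result.contrasts.iterrows():
            contrast_rows.append({"model": name, **row})
        log.info("model %s: %d cells, converged=%s %s",
                 name, len(cells), result.converged, result.flags or "")

    if fit_climate:
        t1 = []
        present = [s for s in SEASONS if (summaries["season"] == s).any()]
        for var in ("mean_temperature", "mean_moisture"):
            for season in present:
                for period in ("diurnal", "nocturnal"):
                    scope = {"season": season, "period": period}
                    res = fit_activity_microclimate_glmm(summaries, var, scope)
                    results[f"climate_{var}_{season}_{period}"] = res
                    for _, row in res.coefficients.iterrows():
                        t1.append(
                            {"climate_var": var, "season": season,
                             "period": period, **row,
                             "converged": res.converged,
                             "flags": ";".join(res.flags)}
                        )
        io.write_table_csv(pd.DataFrame(t1), out / "model_activity_climate.csv")

    io.write_table_csv(pd.DataFrame(coef_rows), out / "model_coefficients.csv")
    io.write_table_csv(pd.DataFrame(contrast_rows), out / "model_contrasts.csv")
    return results


def report_summary_tables(summaries: pd.DataFrame, model_results: dict | None = None) -> pd.DataFrame:
    """Per treatment x season x period mean +/- SD of the headline variables.

    Covers % activity, % activity at photosynthesis-permitting light,
    temperature, moisture and mean efficiency (Yield by day, Fv/Fm by
    night); appends the post-hoc contrast letters where the matching model
    was fitted.  Single-day cells report a mean with SD absent; empty
    cells are absent and logged.
    """
    model_results = model_results or {}
    variables = [
        ("pct_activity", "pct_activity"),
        ("pct_activity_par", "pct_activity_par"),
        ("mean_temperature", "temperature"),
        ("mean_moisture", "moisture"),
        ("mean_efficiency", "efficiency"),
    ]
    rows = []
    for (treatment, season, period), grp in summaries.groupby(
        ["treatment", "season", "period"], sort=True
    ):
        for col, label in variables:
            vals = grp[col].dropna()
            if len(vals) == 0:
                log.warning("empty cell: %s/%s/%s %s", treatment, season, period, label)
                continue
            if label == "efficiency":
                label = "yield" if period == "diurnal" else "fvfm"
            key_model = {
                "pct_activity": f"activity_{period}",
                "pct_activity_par": "activity_par_diurnal"
                if period == "diurnal" else None,
                "mean_temperature": f"temperature_{period}",
                "mean_moisture": f"moisture_{period}",
                "mean_efficiency": f"efficiency_{period}",
            }[col]
            letters = ""
            result = model_results.get(key_model) if key_model else None
            if result is not None and getattr(result, "letters", None):
                letters = result.letters.get(f"{treatment}:{season}", "")
            rows.append(
                {
                    "treatment": treatment,
                    "season": season,
                    "period": period,
                    "variable": label,
                    "n_days": int(len(vals)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "letters": letters,
                }
            )
    return pd.DataFrame(rows)
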