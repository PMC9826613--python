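"""End-to-end run: thermal indices → year comparisons → survey tables →
model selection → diagnostics, with a machine-readable report.

Each stage is executed inside a guard; a failing stage records its
error in the report and downstream stages that depend on it are skipped
with a reason, so a partial run still yields a usable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .envtests import (
    friedman_paired,
    mcnemar_test,
    wilcoxon_signed_rank,
)
from .gls import GlsAr1, heating_rate_design
from .indices import ThermalConfig, compute_mmm_max, thermal_report
from .models import backward_select, brant_test, pairwise_groups
from .simulate import gen_colonies, gen_temperature, scenario_presets
from .survey import bleaching_rate_table, model_frame, read_colony_csv, trajectory_table
from .temperature import align_years, daily_summaries, read_logger_csv

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Inputs and switches for a full pipeline run.

    Either CSV paths (``temp_csvs`` mapping year → logger CSV,
    ``colony_csv``) or a simulation ``preset`` name must be provided.
    """

    temp_csvs: dict = field(default_factory=dict)
    colony_csv: str | None = None
    preset: str | None = None
    alpha: float = 1.0
    heat_window: tuple = ((7, 1), (8, 31))
    hotspot_basis: str = "mean"
    max3d_basis: str = "running_mean"
    compare_to: str = "current"
    adjust: str = "single-step"
    min_obs: int = 20
    out_dir: str | None = None
    seed: int = 0


def _stage(report, name):
    """Decorator-ish guard: run fn, catch and record errors."""

    class _Ctx:
        def __init__(self):
            self.ok = True

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                report["errors"].append({"stage": name, "message": str(exc)})
                self.ok = False
                return True
            return False

    return _Ctx()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the report dict.

    Deterministic given inputs + seed.  The report carries the package
    version, a config echo, per-year thermal indices, year-comparison
    tests, bleaching/trajectory tables, selection traces, Brant tables
    and pairwise mortality contrasts, plus per-stage errors.
    """
    report = {
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "seed": config.seed,
        "errors": [],
    }

    preset = None
    if config.preset:
        preset = scenario_presets(seed=config.seed)[config.preset]

    daily = {}
    with _stage(report, "temperature"):
        if preset is not None:
            series = {y: gen_temperature(c) for y, c in preset.temperature.items()}
        else:
            if not config.temp_csvs:
                raise FileNotFoundError("no temperature inputs configured")
            series = {}
            for year, path in config.temp_csvs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"temperature file missing: {path}")
                series[int(year)] = read_logger_csv(path)
        daily = {y: daily_summaries(s, min_obs=config.min_obs) for y, s in series.items()}

    cfg = None
    with _stage(report, "indices"):
        if not daily:
            raise RuntimeError("skipped: temperature stage failed")
        mmm = compute_mmm_max(daily)
        cfg = ThermalConfig(
            mmm_max=mmm,
            alpha=config.alpha,
            heat_window=config.heat_window,
            hotspot_basis=config.hotspot_basis,
            max3d_basis=config.max3d_basis,
        )
        report["mmm_max"] = mmm
        report["indices"] = {
            str(y): _jsonable(
                {
                    k: v
                    for k, v in thermal_report(d, cfg, y).to_dict().items()
                    if k != "mdhw_running"
                }
            )
            for y, d in daily.items()
        }

    with _stage(report, "compare_temps"):
        if cfg is None or len(daily) < 2:
            raise RuntimeError("skipped: need two years of indices")
        years = sorted(daily)
        a, b = daily[years[0]], daily[years[1]]
        paired = align_years(a, b, window=config.heat_window)
        tests = {}
        for var in ("mean_temp", "max_temp", "min_temp", "dtr"):
            tests[f"friedman_{var}"] = friedman_paired(paired, var).to_dict()
        from .indices import compute_mdhw, hotspots

        run_a, _ = compute_mdhw(hotspots(a, cfg), cfg)
        run_b, _ = compute_mdhw(hotspots(b, cfg), cfg)
        md = pd.DataFrame(
            {
                "a": {(d.month, d.day): v for d, v in run_a.items()},
                "b": {(d.month, d.day): v for d, v in run_b.items()},
            }
        ).dropna()
        tests["wilcoxon_mdhw"] = wilcoxon_signed_rank(md["a"], md["b"]).to_dict()
        hs_a = hotspots(a, cfg, window="year")
        hs_b = hotspots(b, cfg, window="year")
        ex = pd.DataFrame(
            {
                "a": {(d.month, d.day): v >= cfg.alpha for d, v in hs_a.items()},
                "b": {(d.month, d.day): v >= cfg.alpha for d, v in hs_b.items()},
            }
        ).dropna()
        tab = [
            [int((ex["a"] & ex["b"]).sum()), int((ex["a"] & ~ex["b"]).sum())],
            [int((~ex["a"] & ex["b"]).sum()), int((~ex["a"] & ~ex["b"]).sum())],
        ]
        try:
            tests["mcnemar_acute1"] = mcnemar_test(tab).to_dict()
        except Exception as err:  # degenerate: no discordant days
            tests["mcnemar_acute1"] = {"error": str(err)}
        X, yv, groups = heating_rate_design(a, b)
        fit = GlsAr1().fit(X, yv, groups=groups)
        z, p = fit.wald("time:year")
        tests["gls_heating_rate"] = {
            "coefficients": _jsonable(fit.coef_),
            "rho": fit.rho_,
            "interaction_z": z,
            "interaction_p": p,
            "n": fit.n_,
        }
        report["comparisons"] = _jsonable(tests)

    records = None
    with _stage(report, "survey"):
        if preset is not None:
            records = gen_colonies(preset.colonies)
        elif config.colony_csv:
            records = read_colony_csv(config.colony_csv)
        else:
            raise FileNotFoundError("no colony inputs configured")
        report["bleaching_rates"] = {
            str(y): _jsonable(bleaching_rate_table(records, y)) for y in (2016, 2017)
        }
        report["trajectories"] = _jsonable(trajectory_table(records))

    with _stage(report, "models"):
        if records is None:
            raise RuntimeError("skipped: survey stage failed")
        models = {}

        frame = model_frame(records, "bleaching")
        best, trace = backward_select(
            frame, "y", ["size", "group", "time"], "ordinal", compare_to=config.compare_to
        )
        entry = {"best_terms": best.terms, "trace": _jsonable(trace), "n": best.n}
        if best.terms and best.family == "ordinal":
            br = brant_test(best.estimator, best.X, best.y)
            entry["brant"] = _jsonable(br.to_frame())
        models["bleaching"] = entry

        frame17 = model_frame(records, "bleaching2017")
        best17, trace17 = backward_select(
            frame17, "y", ["group", "growth", "size"], "ordinal", compare_to=config.compare_to
        )
        models["bleaching2017"] = {
            "best_terms": best17.terms,
            "trace": _jsonable(trace17),
            "n": best17.n,
        }

        for resp, terms in (
            ("whole_mortality", ["size", "group", "time", "size:time", "size:group", "group:time", "size:group:time"]),
            ("partial_mortality", ["size", "group", "time", "size:time", "size:group", "group:time", "size:group:time"]),
        ):
            fr = model_frame(records, resp)
            bm, tr = backward_select(fr, "y", terms, "binomial", compare_to=config.compare_to)
            entry = {"best_terms": bm.terms, "trace": _jsonable(tr), "n": bm.n}
            if "group" in bm.terms:
                entry["pairwise_group"] = _jsonable(
                    pairwise_groups(bm, "group", adjust=config.adjust)
                )
            models[resp] = entry
        report["models"] = models

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
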