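"""Configuration-driven orchestration of the analysis stages.

``run_pipeline`` takes a plain config mapping (typically loaded from
YAML), dispatches to one stage — simulate, sweep, fit, pathstats, or one
of the synthetic generators — writes the stage outputs, and records a
manifest (command, config snapshot, seed, package version, output files,
timestamps).  A run is reproducible from its manifest: feeding the
snapshot back into ``run_pipeline`` regenerates the outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cr_models import GrowthSeries
from .fitting import (
    DEFAULT_KN,
    DEFAULT_R0,
    compare_models,
    fit_consumer_resource,
    fit_logistic,
    mean_across_replicates,
)
from .simulator import SimConfig, run_simulation, sweep
from .synthetic import (
    DEFAULT_CIRC_SD,
    SamplingDesign,
    generate_core_margin_scenario,
    generate_crw_paths,
    generate_growth_curves,
    CORE_TRUTH,
)
from .trajectory import DEFAULT_FPS, read_paths_csv, summarize_paths, write_paths_csv

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "read_growth_curves_csv", "write_growth_curves_csv"]

COMMANDS = ("simulate", "sweep", "fit", "pathstats", "synth", "scenario")


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    version: str
    outputs: list[str]
    started: str
    finished: str

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def read_growth_curves_csv(path) -> dict[str, list[GrowthSeries]]:
    """Read growth curves grouped by treatment (and replicate, if present).

    Expected columns: ``time_h, density_per_ml`` plus optional
    ``treatment`` and ``replicate`` grouping columns.
    """
    df = pd.read_csv(path)
    for col in ("time_h", "density_per_ml"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
        if df[col].isna().any():
            raise ValueError(f"missing values in column {col!r} of {path}")
    if "treatment" not in df.columns:
        df["treatment"] = "all"
    if "replicate" not in df.columns:
        df["replicate"] = 0
    out: dict[str, list[GrowthSeries]] = {}
    for (trt, rep), grp in df.groupby(["treatment", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.setdefault(str(trt), []).append(
            GrowthSeries(
                grp["time_h"].to_numpy(), grp["density_per_ml"].to_numpy(),
                label=f"{trt}/{rep}",
            )
        )
    return out


def write_growth_curves_csv(curves: dict[str, list[GrowthSeries]], path) -> None:
    frames = []
    for trt, series in curves.items():
        for rep, s in enumerate(series):
            frames.append(
                pd.DataFrame(
                    {
                        "treatment": trt,
                        "replicate": rep,
                        "time_h": s.times,
                        "density_per_ml": s.densities,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _fit_one(series: GrowthSeries, model: str, r0: float, KN: float) -> dict:
    report: dict = {"n_obs": len(series)}
    fits = {}
    if model in ("logistic", "both"):
        fits["logistic"] = fit_logistic(series)
    if model in ("cr", "both"):
        fits["consumer_resource"] = fit_consumer_resource(series, fixed_r0=r0, fixed_KN=KN)
    for name, fr in fits.items():
        report[name] = {
            "params": fr.params, "fixed": fr.fixed,
            "rss": fr.rss, "aic": fr.aic, "k_free": fr.k_free,
        }
    if len(fits) == 2:
        cmp_ = compare_models(fits["logistic"], fits["consumer_resource"])
        report["delta_aic"] = cmp_.delta_aic
        report["preferred"] = cmp_.preferred
    report["_fits"] = fits
    return report


def _stage_fit(config: dict, out_dir: Path) -> list[str]:
    curves = read_growth_curves_csv(config["input"])
    model = config.get("model", "both")
    if model not in ("logistic", "cr", "both"):
        raise ValueError(f"unknown model {model!r}")
    r0 = float(config.get("r0", DEFAULT_R0))
    KN = float(config.get("KN", DEFAULT_KN))
    per_replicate = bool(config.get("per_replicate", False))

    reports, pred_frames = {}, []
    for trt, series_list in curves.items():
        targets = (
            {f"{trt}/rep{i}": s for i, s in enumerate(series_list)}
            if per_replicate
            else {trt: mean_across_replicates(series_list, label=trt)}
        )
        for label, series in targets.items():
            rep = _fit_one(series, model, r0, KN)
            fits = rep.pop("_fits")
            reports[label] = rep
            grid = np.linspace(series.times[0], series.times[-1], 200)
            for name, fr in fits.items():
                pred_frames.append(
                    pd.DataFrame(
                        {"treatment": label, "model": name,
                         "time_h": grid, "density_per_ml": fr.predict(grid)}
                    )
                )

    fits_json = out_dir / "fits.json"
    fits_json.write_text(json.dumps(reports, indent=2))
    pred_csv = out_dir / "predicted_curves.csv"
    pd.concat(pred_frames, ignore_index=True).to_csv(pred_csv, index=False)
    return [str(fits_json), str(pred_csv)]


def _stage_simulate(config: dict, out_dir: Path) -> list[str]:
    cfg = SimConfig(**config.get("simulate", {}))
    record_every = int(config.get("record_every", 0))
    res = run_simulation(cfg, record_every=record_every)
    outputs = []
    profile_csv = out_dir / "profile.csv"
    res.profile.to_csv(profile_csv, index=False)
    outputs.append(str(profile_csv))
    if res.records is not None:
        rec_csv = out_dir / "records.csv"
        res.records.to_csv(rec_csv, index=False)
        outputs.append(str(rec_csv))
    front_csv = out_dir / "front.csv"
    pd.DataFrame(
        {"generation": np.arange(1, res.front_history.size + 1),
         "front": res.front_history}
    ).to_csv(front_csv, index=False)
    outputs.append(str(front_csv))
    summary = out_dir / "run_summary.json"
    summary.write_text(json.dumps(
        {"completed": res.completed, "extinct": res.extinct,
         "generations": res.generations}, indent=2))
    outputs.append(str(summary))
    return outputs


def _stage_sweep(config: dict, out_dir: Path) -> list[str]:
    base = SimConfig(**config.get("simulate", {}))
    profiles, agg = sweep(
        grid=config.get("grid"),
        n_replicates=int(config.get("replicates", 20)),
        seed=int(config.get("seed", 0)),
        base=base,
    )
    p_csv, a_csv = out_dir / "profiles.csv", out_dir / "profiles_aggregated.csv"
    profiles.to_csv(p_csv, index=False)
    agg.to_csv(a_csv, index=False)
    return [str(p_csv), str(a_csv)]


def _stage_pathstats(config: dict, out_dir: Path) -> list[str]:
    paths = read_paths_csv(config["input"], fps=float(config.get("fps", DEFAULT_FPS)))
    stats = summarize_paths(paths, min_duration=float(config.get("min_duration", 4.0)))
    out_csv = out_dir / "path_stats.csv"
    stats.to_csv(out_csv, index=False)
    return [str(out_csv)]


def _stage_synth(config: dict, out_dir: Path) -> list[str]:
    what = config.get("what", "scenario")
    seed = int(config.get("seed", 0))
    outputs = []
    if what == "growth":
        truth = config.get("truth", CORE_TRUTH)
        if isinstance(truth, dict):
            from .cr_models import CRParams

            truth = CRParams(**truth)
        reps, true_series, _ = generate_growth_curves(
            truth,
            SamplingDesign(),
            n_replicates=int(config.get("replicates", 6)),
            seed=seed,
        )
        out_csv = out_dir / "growth_curves.csv"
        write_growth_curves_csv({"synthetic": reps}, out_csv)
        outputs.append(str(out_csv))
    elif what == "paths":
        paths = generate_crw_paths(
            speed=float(config.get("speed", 300.0)),
            circ_sd=float(config.get("circ_sd", DEFAULT_CIRC_SD)),
            n_paths=int(config.get("n_paths", 100)),
            seed=seed,
        )
        out_csv = out_dir / "paths.csv"
        write_paths_csv(paths, out_csv)
        outputs.append(str(out_csv))
    elif what == "scenario":
        sc = generate_core_margin_scenario(
            seed=seed,
            n_replicates=int(config.get("replicates", 6)),
            n_paths=int(config.get("n_paths", 40)),
            equal_truth=bool(config.get("equal_truth", False)),
        )
        g_csv = out_dir / "growth_curves.csv"
        write_growth_curves_csv(sc.growth, g_csv)
        outputs.append(str(g_csv))
        for label, paths in sc.paths.items():
            p_csv = out_dir / f"paths_{label}.csv"
            write_paths_csv(paths, p_csv)
            outputs.append(str(p_csv))
    else:
        raise ValueError(f"unknown synth target {what!r}")
    return outputs


_STAGES = {
    "simulate": _stage_simulate,
    "sweep": _stage_sweep,
    "fit": _stage_fit,
    "pathstats": _stage_pathstats,
    "synth": _stage_synth,
    "scenario": lambda cfg, out: _stage_synth({**cfg, "what": "scenario"}, out),
}


def run_pipeline(config: dict, out_dir="ecorange_out") -> RunManifest:
    """Dispatch one stage and write its outputs plus a run manifest."""
    command = config.get("command")
    if command not in _STAGES:
        raise ValueError(f"unknown command {command!r}; expected one of {sorted(_STAGES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now().isoformat(timespec="seconds")
    logger.info("running stage %s -> %s", command, out_dir)
    outputs = _STAGES[command](config, out_dir)
    finished = _dt.datetime.now().isoformat(timespec="seconds")
    manifest = RunManifest(
        command=command,
        config={k: v for k, v in config.items() if not k.startswith("_")},
        seed=config.get("seed", config.get("simulate", {}).get("seed")),
        version=__version__,
        outputs=outputs,
        started=started,
        finished=finished,
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
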