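"""End-to-end orchestration: data, summaries, models, simulations, report.

One global seed spawns per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is individually
reproducible and the whole run is byte-identical for identical
(config, seed).  Stage failures are recorded in the run manifest;
stages that do not depend on the failed one still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import crossing, encounters as enc, evolution, mortality, synth

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("data", "summarize", "fit", "crossing", "differential", "evolve")


@dataclass
class PipelineConfig:
    out_dir: str | Path
    seed: int = 0
    encounters_path: str | None = None
    efforts_path: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    adult_svl_min: float | None = 40.0
    n_crossing_trials: int = 10_000
    two_car_placement: str = "uniform_on_road"
    n_boot: int = 1000
    evo: evolution.EvoSimConfig = field(default_factory=evolution.EvoSimConfig)
    use_estimated_s: bool = True

    def __post_init__(self):
        real = self.encounters_path is not None
        if real and self.efforts_path is None:
            raise ValueError("efforts_path is required with encounters_path")
        if real and self.synthetic is not None:
            raise ValueError("supply either data paths or a synthetic config, not both")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "evo" in raw and isinstance(raw["evo"], dict):
            raw["evo"] = evolution.EvoSimConfig(**raw["evo"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write per-stage outputs plus ``manifest.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    child = dict(zip(_STAGES, ss.spawn(len(_STAGES))))
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "config": _jsonify({k: v for k, v in dataclasses.asdict(config).items()
                            if k != "synthetic"}),
    }
    results: dict = {}

    def stage(name, func, depends=()):
        missing = [d for d in depends if manifest["stages"].get(d, {}).get("status") != "ok"]
        if missing:
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": f"dependency failed: {missing}"}
            return
        try:
            func()
            manifest["stages"][name] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001 - recorded in the manifest
            manifest["stages"][name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=3),
            }

    def _data():
        if config.encounters_path:
            results["encounters"] = enc.read_encounters(config.encounters_path)
            results["efforts"] = enc.read_efforts(config.efforts_path)
        else:
            cfg = config.synthetic or synth.default_config()
            results["encounters"], results["efforts"] = synth.generate_community(
                cfg, child["data"])
        enc.write_encounters(results["encounters"], out / "encounters.csv")
        enc.write_efforts(results["efforts"], out / "efforts.csv")

    def _summarize():
        es, fs = results["encounters"], results["efforts"]
        std = [e for e in es if e.survey_type == "standardized"]
        std_eff = [f for f in fs if f.survey_type == "standardized"]
        enc.monthly_summary(std, std_eff).to_csv(out / "monthly_summary.csv")
        enc.species_morphometry(es).to_csv(out / "morphometry.csv", index=False)
        counts, edges, n_skipped = enc.bin_route_positions(std)
        import pandas as pd

        pd.DataFrame({"bin_low_km": edges[:-1], "bin_high_km": edges[1:],
                      "count": counts}).to_csv(out / "bins.csv", index=False)
        stat, df, p = enc.uniformity_chi_square(counts, np.diff(edges))
        (out / "chi_square.json").write_text(json.dumps(
            {"statistic": stat, "df": df, "p_value": p, "n_skipped": n_skipped},
            indent=2))

    def _fit():
        frame = synth.encounters_to_model_frame(
            enc.filter_adult_atrox(results["encounters"], svl_min=config.adult_svl_min))
        results["adult_frame"] = frame
        ranking = mortality.rank_models(frame, mortality.STUDY_MODEL_SET)
        if ranking.empty:
            raise RuntimeError("no candidate model converged")
        ranking.to_csv(out / "model_ranking.csv", index=False)
        top = ranking.attrs["fits"][ranking.loc[0, "model"]]
        results["top_fit"] = top
        ors = mortality.odds_ratios(top)
        summary = {
            "model": top.spec.label,
            "n": top.n, "df": top.df,
            "loglik": top.loglik, "aic": top.aic,
            "auc": mortality.auc(top),
            "estimates": top.params.to_dict(),
            "odds_ratios": ors.to_dict(orient="records"),
        }
        (out / "top_fit.json").write_text(json.dumps(_jsonify(summary), indent=2))
        if "total_length" in top.spec.variables:
            curve = mortality.prediction_curve(top)
            curve.to_csv(out / "curve.csv", index=False)
            used = top.data
            spline = mortality.cubic_spline_probability(
                used["total_length"].to_numpy(),
                np.asarray(top.result.predict(used)),
                seed=child["fit"])
            spline.to_csv(out / "spline.csv", index=False)
            lg = np.linspace(used["total_length"].min(), used["total_length"].max(), 40)
            wg = np.linspace(used["weight"].min(), used["weight"].max(), 40)
            mortality.selection_surface(top, lg, wg).to_csv(
                out / "surface.csv", index=False)

    def _crossing():
        seeds = child["crossing"].spawn(2)
        summary = {}
        for scenario, seed in zip(("one_car", "two_car"), seeds):
            placement = None if scenario == "one_car" else config.two_car_placement
            res = crossing.simulate_crossings(
                scenario=scenario, n_trials=config.n_crossing_trials,
                seed=seed, placement=placement)
            summary[scenario] = {
                "mean": res.mean, "sd": res.sd,
                "ci": [res.ci_low, res.ci_high],
                "n_trials": res.n_trials, "placement": res.placement,
            }
            crossing.mortality_by_length_curve(res).to_csv(
                out / f"crossing_curve_{scenario}.csv", index=False)
        (out / "crossing_summary.json").write_text(json.dumps(_jsonify(summary), indent=2))
        results["crossing"] = summary

    def _differential():
        frame = results.get("adult_frame")
        if frame is None:
            frame = synth.encounters_to_model_frame(
                enc.filter_adult_atrox(results["encounters"],
                                       svl_min=config.adult_svl_min,
                                       require={"svl", "tail"}))
        est = evolution.bootstrap_differential(
            frame["total_length"].to_numpy(),
            np.where(frame["dor"] == 1, "DOR", "AOR"),
            n_boot=config.n_boot, seed=child["differential"])
        results["differential"] = est
        (out / "selection_differential.json").write_text(
            json.dumps(_jsonify(est), indent=2))

    def _evolve():
        evo = config.evo
        est = results.get("differential")
        if config.use_estimated_s and est is not None:
            evo = dataclasses.replace(evo, s_mean=est.s, s_sd=est.sd_boot)
        # spawn a child integer seed for the EvoSimConfig
        evo = dataclasses.replace(
            evo, seed=int(np.random.default_rng(child["evolve"]).integers(2**31 - 1)))
        traj = evolution.simulate_response(evo)
        traj.to_frame().to_csv(out / "trajectories.csv", index=False)
        summary = evolution.summarize_trajectories(traj)
        curve = summary.pop("curve")
        curve.to_csv(out / "evolution_curve.csv", index=False)
        slope, intercept, p = evolution.h2_final_regression(traj)
        summary.update({
            "h2_slope": slope, "h2_intercept": intercept, "h2_p_value": p,
            "years": evolution.generations_to_years(evo.n_gens, evo.generation_time_yr),
        })
        (out / "evolution_summary.json").write_text(json.dumps(_jsonify(summary), indent=2))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage("data", _data)
        stage("summarize", _summarize, depends=("data",))
        stage("fit", _fit, depends=("data",))
        stage("crossing", _crossing)
        stage("differential", _differential, depends=("data",))
        stage("evolve", _evolve)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(_jsonify(manifest), indent=2, sort_keys=True))
    return manifest
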