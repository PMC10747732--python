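"""End-to-end orchestration: cohort -> kinematics -> sensors -> features -> models.

The stages are pure functions over an explicit :class:`RunConfig`; every
stochastic stage derives its seed deterministically from the master seed
and the stage name, so a config fully determines every artifact.  Stage
outputs are plain CSV tables (with a JSON manifest recording the config,
seeds and column provenance), which keeps each stage independently
inspectable and re-runnable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, GroundTruthForces, RunnerProfile, TrialSpec,
                     derive_seed, ground_truth_forces, sample_cohort,
                     sample_trials, synthesize_kinematics)
from .evaluate import (TARGETS, calibration_stats, enet_importance,
                       evaluate_grid, gbt_importance, select_best, summarize)
from .features import (SENSOR_CONFIGURATIONS, DesignMatrix,
                       build_design_matrix, compress_trace)
from .models import ElasticNetSpec, GbtSpec
from .virtual_imu import DEFAULT_SAMPLE_RATE, build_chain, emulate_all_sites


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    master_seed: int = 0
    n_runners: int = 78
    n_trials: int = 285
    speed_range: tuple = (6.0, 20.0)
    sample_rate: float = DEFAULT_SAMPLE_RATE
    config_ids: tuple = (1, 2, 3, 4, 5, 6, 7)
    n_splits: int = 250
    train_frac: float = 0.9
    calibration_subsample: int = 250
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speed_range"] = list(self.speed_range)
        d["config_ids"] = list(self.config_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cd = dict(d["cohort"])
            from .cohort import SexParams
            for sex in ("female", "male"):
                if sex in cd and isinstance(cd[sex], dict):
                    cd[sex] = SexParams(**cd[sex])
            for key in ("speed_range", "duty_clip", "heel_lever",
                        "forefoot_lever"):
                if key in cd and isinstance(cd[key], list):
                    cd[key] = tuple(cd[key])
            d["cohort"] = CohortConfig(**cd)
        for key in ("speed_range", "config_ids"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimulatedDataset:
    """In-memory bundle of one simulated study."""

    config: RunConfig
    profiles: list
    trials: list
    kinematics: dict       # trial_id -> TrialKinematics
    forces: dict           # trial_id -> GroundTruthForces
    accel_codes: dict      # trial_id -> site -> channel -> FourierCode
    design_matrices: dict  # config_id -> DesignMatrix

    @property
    def profile_map(self) -> dict:
        return {p.runner_id: p for p in self.profiles}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_dataset(config: RunConfig) -> SimulatedDataset:
    """Run the simulation stages: cohort, trials, kinematics, sensors, features."""
    seed = config.master_seed
    profiles = sample_cohort(config.n_runners, derive_seed(seed, "cohort"),
                             config.cohort)
    trials = sample_trials(profiles, config.n_trials, config.speed_range,
                           derive_seed(seed, "trials"), config.cohort)
    profile_map = {p.runner_id: p for p in profiles}

    kinematics, forces, accel_codes = {}, {}, {}
    chains = {}
    for trial in trials:
        prof = profile_map[trial.runner_id]
        kin = synthesize_kinematics(prof, trial,
                                    derive_seed(seed, "kinematics"),
                                    config.cohort)
        kinematics[trial.trial_id] = kin
        forces[trial.trial_id] = ground_truth_forces(prof, trial, kin,
                                                     config.cohort)
        if trial.runner_id not in chains:
            chains[trial.runner_id] = build_chain(prof)
        traces = emulate_all_sites(
            chains[trial.runner_id], kin, sample_rate=config.sample_rate,
            noise_sd=config.cohort.noise_sd,
            seed=derive_seed(seed, "noise", trial.trial_id))
        accel_codes[trial.trial_id] = {
            site: compress_trace(trace, kin.fundamental_frequency)
            for site, trace in traces.items()
        }

    design_matrices = {
        cid: build_design_matrix(trials, accel_codes, profile_map,
                                 SENSOR_CONFIGURATIONS[cid], forces)
        for cid in config.config_ids
    }
    return SimulatedDataset(config=config, profiles=profiles, trials=trials,
                            kinematics=kinematics, forces=forces,
                            accel_codes=accel_codes,
                            design_matrices=design_matrices)


def cohort_table(profiles: list) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


def trial_table(trials: list) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in trials])


def force_table(forces: dict) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in forces.values()])


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the result bundle to ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).  Re-running
    with the same config writes byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)

    cohort_table(data.profiles).to_csv(out / "cohort.csv", index=False)
    trial_table(data.trials).to_csv(out / "trials.csv", index=False)
    force_table(data.forces).to_csv(out / "forces.csv", index=False)

    for cid, dm in data.design_matrices.items():
        frame = dm.X.copy()
        frame.insert(0, "trial_id", dm.trial_ids)
        frame["patella"] = dm.targets["patella"].to_numpy()
        frame["achilles"] = dm.targets["achilles"].to_numpy()
        frame.to_csv(out / f"design_config{cid}.csv", index=False)
        sidecar = {
            "config_id": cid,
            "sites": list(dm.config.sites),
            "n_predictors": len(dm.column_names),
            "predictors": dm.column_names,
            "master_seed": config.master_seed,
        }
        (out / f"design_config{cid}.json").write_text(
            json.dumps(sidecar, indent=1))

    table, details = evaluate_grid(
        data.design_matrices, n_splits=config.n_splits,
        train_frac=config.train_frac,
        seed=derive_seed(config.master_seed, "evaluate"),
        collect_importance=True)
    table.to_csv(out / "evaluation.csv", index=False, float_format="%.6f")

    best = select_best(table)
    importance, calibration = {}, {}
    for target, row in best.items():
        cid = int(row["config_id"])
        dm = data.design_matrices[cid]
        cell = next(c for c in details
                    if c.target == target and c.config_id == cid
                    and c.model_label == row["model"])
        results = details[cell]
        if row["family"] == "elastic_net":
            rep = enet_importance(results, dm.column_names)
        else:
            rep = gbt_importance(results, dm.column_names)
        importance[target] = {
            "model": row["model"], "config_id": cid,
            "report": rep.as_frame().to_dict(orient="list"),
            "below_10pct": rep.below_10pct,
            "at_least_90pct": rep.at_least_90pct,
        }
        calibration[target] = _best_cell_calibration(data, config, row)

    (out / "importance.json").write_text(json.dumps(importance, indent=1))
    (out / "calibration.json").write_text(json.dumps(calibration, indent=1))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            name: derive_seed(config.master_seed, name)
            for name in ("cohort", "trials", "kinematics", "evaluate")
        },
        "n_runners": len(data.profiles),
        "n_trials": len(data.trials),
        "design_matrix_columns": {
            cid: len(dm.column_names)
            for cid, dm in data.design_matrices.items()},
        "best": {t: {k: (v if not isinstance(v, float) else float(v))
                     for k, v in row.items()} for t, row in best.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _spec_from_row(row) -> object:
    label = row["model"]
    if row["family"] == "elastic_net":
        return ElasticNetSpec(alpha=float(label.split("a=")[1]))
    depth = int(label.split("d=")[1].split()[0])
    eta = float(label.split("eta=")[1])
    return GbtSpec(depth=depth, learning_rate=eta)


def _best_cell_calibration(data: SimulatedDataset, config: RunConfig,
                           row) -> dict:
    """Pooled-test-point calibration line for one winning grid cell."""
    from .evaluate import _fit_for_spec
    from .models import predict as model_predict

    cid = int(row["config_id"])
    dm = data.design_matrices[cid]
    target = row["target"]
    y = dm.targets[target].to_numpy()
    spec = _spec_from_row(row)
    seed = derive_seed(config.master_seed, "calibration", target)

    pooled_pred, pooled_obs = [], []
    n = y.size
    n_train = int(round(config.train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    n_splits = max(1, int(np.ceil(2 * config.calibration_subsample
                                  / max(n - n_train, 1))))
    for i in range(n_splits):
        perm = np.random.default_rng(derive_seed(seed, "split", i)).permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = _fit_for_spec(dm.X.iloc[tr], y[tr], spec,
                              derive_seed(seed, "fit", i))
        pooled_pred.append(np.asarray(model_predict(model, dm.X.iloc[te])))
        pooled_obs.append(y[te])
    pred = np.concatenate(pooled_pred)
    obs = np.concatenate(pooled_obs)
    sub = min(config.calibration_subsample, pred.size)
    cal = calibration_stats(pred, obs, subsample=sub, seed=seed)
    return {"intercept": cal.intercept, "slope": cal.slope,
            "n_pooled": int(pred.size), "subsample": sub,
            "degenerate": cal.degenerate}


def make_fixture(size: str = "tiny", seed: int = 0) -> SimulatedDataset:
    """Small packaged dataset for tests and demos (no downloads).

    ``tiny`` = 8 runners / 20 trials with the reduced evaluation profile;
    ``default`` = the full 78-runner / 285-trial replication shape.
    """
    if size == "tiny":
        cfg = RunConfig(master_seed=seed, n_runners=8, n_trials=20,
                        n_splits=10)
    elif size == "default":
        cfg = RunConfig(master_seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    return simulate_dataset(cfg)
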