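"""End-to-end orchestration: simulate -> harmonize -> hopkins -> select-K ->
fit -> assign -> characterize, with one master seed, per-stage artifacts and
a run manifest of digests for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import DEFAULT_ATLAS
from .characterize import (
    bin_duration,
    stage_correlates,
    symptom_trajectory,
)
from .harmonize import harmonize_cohort
from .model import FitSettings, assign, fit
from .selection import hopkins, select_K
from .simulate import (
    SimulationConfig,
    generate_clinical,
    generate_cohort,
    write_cohort,
)

log = logging.getLogger("zsustain")

STAGES = (
    "simulate",
    "harmonize",
    "hopkins",
    "select_k",
    "fit",
    "assign",
    "characterize",
)


@dataclass
class RunConfig:
    """Run-level configuration; every random step derives from one seed."""

    out_dir: str = "zsustain_run"
    seed: int = 0
    n_patients: int = 800
    n_controls: int = 800
    waypoints: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    k_range: tuple[int, ...] = (2, 3, 4)
    k_fit: int | None = None  # None -> the K chosen by select_k
    n_repeats: int = 3
    settings: FitSettings = field(default_factory=FitSettings)
    cv_settings: FitSettings = field(
        default_factory=lambda: FitSettings(n_starts=2, n_mcmc=0, split_restarts=4)
    )
    hopkins_m: int | None = None
    resume: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("settings", "cv_settings"):
            if key in d and isinstance(d[key], dict):
                d[key] = FitSettings(**d[key])
        for key in ("waypoints", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list = field(default_factory=list)  # {name, artifacts{path: digest}, seconds, seed}

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @property
    def completed(self) -> list:
        return [s["name"] for s in self.stages]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, writing artifacts under ``config.out_dir``.

    With ``resume=True``, stages whose artifacts already exist are reloaded
    instead of recomputed.  A stage failure writes a manifest of the stages
    completed so far and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = DEFAULT_ATLAS
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(len(STAGES))
    ]
    stage_seed = dict(zip(STAGES, seeds))
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__, seed=config.seed
    )
    state: dict = {}

    def record(name: str, artifacts: list[Path], t0: float) -> None:
        manifest.stages.append(
            {
                "name": name,
                "seed": stage_seed[name],
                "seconds": round(time.time() - t0, 3),
                "artifacts": {str(p): _digest(p) for p in artifacts},
            }
        )

    def stage_simulate():
        path = out / "cohort.tsv"
        if config.resume and path.exists():
            from .simulate import read_cohort

            state["cohort"] = read_cohort(path)
            return [path]
        sim = SimulationConfig(
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            waypoints=config.waypoints,
            z_max=config.z_max,
            seed=stage_seed["simulate"],
        )
        cohort = generate_clinical(generate_cohort(sim, atlas), sim, atlas)
        state["cohort"] = cohort
        write_cohort(cohort, path)
        return [path, path.with_suffix(path.suffix + ".columns.json")]

    def stage_harmonize():
        z, report, _ = harmonize_cohort(state["cohort"], atlas)
        state["z"] = z
        zpath = out / "zscores.tsv"
        meta = state["cohort"].loc[z.values.index, ["subject_id", "group"]]
        pd.concat([meta, z.values], axis=1).to_csv(zpath, sep="\t", index=False)
        rpath = out / "outliers.json"
        report.to_json(rpath)
        return [zpath, rpath]

    def stage_hopkins():
        zpat = state["z"].patients.to_numpy()
        res = hopkins(zpat, m=config.hopkins_m, seed=stage_seed["hopkins"])
        path = out / "hopkins.json"
        path.write_text(
            json.dumps(
                {
                    "H": res.H,
                    "m": res.m,
                    "confidence_level": res.confidence_level,
                    "clustered": bool(res.clustered),
                },
                indent=2,
            )
        )
        state["hopkins"] = res
        return [path]

    def stage_select_k():
        zpat = state["z"].patients.to_numpy()
        spec = _spec(config, atlas)
        curve = select_K(
            zpat,
            spec,
            k_range=config.k_range,
            n_repeats=config.n_repeats,
            settings=config.cv_settings,
            seed=stage_seed["select_k"],
        )
        path = out / "dice_curve.json"
        path.write_text(json.dumps(curve.to_dict(), indent=2))
        state["curve"] = curve
        return [path]

    def stage_fit():
        zpat = state["z"].patients.to_numpy()
        spec = _spec(config, atlas)
        K = config.k_fit or state["curve"].chosen_k
        model = fit(zpat, K, spec, config.settings, seed=stage_seed["fit"])
        state["model"] = model
        path = out / "model.json"
        path.write_text(json.dumps(model.to_dict(), indent=2))
        return [path]

    def stage_assign():
        zpat = state["z"].patients
        asg = assign(zpat.to_numpy(), state["model"])
        state["assign"] = asg
        path = out / "assignments.tsv"
        ids = state["cohort"].loc[zpat.index, "subject_id"].to_numpy()
        asg.to_frame(index=ids).rename_axis("subject_id").to_csv(path, sep="\t")
        return [path]

    def stage_characterize():
        zpat = state["z"].patients
        cohort = state["cohort"].loc[zpat.index]
        asg = state["assign"]
        artifacts = []
        measures = zpat.copy()
        if "illness_duration" in cohort.columns:
            measures = pd.concat(
                [measures, cohort.filter(regex="^(illness_duration|panss_)")], axis=1
            )
        corr = stage_correlates(asg.stages, measures)
        p1 = out / "stage_correlates.tsv"
        corr.rename_axis("measure").to_csv(p1, sep="\t")
        artifacts.append(p1)
        if "illness_duration" in cohort.columns and asg.proba.shape[1] >= 2:
            clin = cohort.assign(stage=asg.stages)
            bins = bin_duration(clin["illness_duration"])
            traj = symptom_trajectory(clin, asg.labels, bins)
            for name, df in traj.items():
                p = out / f"symptoms_{name}.tsv"
                df.to_csv(p, sep="\t", index=False)
                artifacts.append(p)
        return artifacts

    runners = {
        "simulate": stage_simulate,
        "harmonize": stage_harmonize,
        "hopkins": stage_hopkins,
        "select_k": stage_select_k,
        "fit": stage_fit,
        "assign": stage_assign,
        "characterize": stage_characterize,
    }
    try:
        for name in STAGES:
            t0 = time.time()
            log.info("stage %s", name)
            artifacts = runners[name]()
            record(name, [Path(p) for p in artifacts], t0)
    finally:
        manifest.to_json(out / "manifest.json")
    return manifest


def _spec(config: RunConfig, atlas):
    from .simulate import event_spec_for

    return event_spec_for(atlas, tuple(config.waypoints), config.z_max)
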