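"""End-to-end pipeline: configuration, seeding, stage orchestration.

The pipeline chains the package's stages — fit (or accept) a motion
model, simulate stimuli, enumerate a design, simulate observers, fit
the SDT probit model — under a single root seed.  Per-stage seeds are
derived from the root seed with ``numpy.random.SeedSequence``, so a
fixed root seed reproduces every stage bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import inference, motion, observer, stimuli
from .errors import InvalidInputError
from .trajectory import write_trajectories_csv

__all__ = ["PipelineConfig", "SchemaError", "run_end_to_end", "make_fixtures", "default_motion_model"]

log = logging.getLogger("fishmot")


class SchemaError(InvalidInputError):
    """Configuration violates the schema; the message names the field."""


def default_motion_model() -> motion.MotionModel:
    """Reference fish-like motion law used when no fitted model is given.

    Gamma parameters chosen to emulate the observed aquarium kinematics,
    chiefly the ~20%/80% wait/move time split: waits of ~0.5 s, dashes
    of ~150 px travelled at ~100 px/s (so movement phases last ~2 s).
    The positional jitter during waits (3 px) is kept well below any
    segmentation radius so waits remain detectable.
    """
    return motion.MotionModel(
        wait_duration=motion.GammaFit(k=2.0, theta=0.25, n=0, loglik=0.0),
        dash_distance=motion.GammaFit(k=2.5, theta=60.0, n=0, loglik=0.0),
        dash_velocity=motion.GammaFit(k=4.0, theta=25.0, n=0, loglik=0.0),
        jitter_radius=3.0,
    )


@dataclass
class ArenaConfig:
    diameter: float = 800.0
    center: tuple = (960.0, 600.0)
    scene_extent: tuple = (1920.0, 1200.0)


@dataclass
class SimSection:
    n_objects: int = 8
    duration: float = 10.0
    dt: float = 1.0 / 30.0
    speed: float = 200.0
    object_radius: float = 16.0


@dataclass
class DesignSection:
    n_videos: int = 23
    set_sizes: tuple = (1, 3, 5)
    loads_exp2: tuple = (2, 4)
    n_objects: int = 16


@dataclass
class PopulationSection:
    alpha_d: float = 3.58
    beta_d: float = -0.50
    alpha_c: float = 1.97
    beta_c: float = -0.22
    sigma_ad: float = 0.5
    sigma_bd: float = 0.1
    sigma_ac: float = 0.3
    sigma_bc: float = 0.05
    n_participants: int = 4


@dataclass
class SamplerSection:
    n_chains: int = 2
    warmup: int = 300
    draws: int = 500
    prior_sd: float = 1.0


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_end_to_end`."""

    seed: int = 1
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    sim: SimSection = field(default_factory=SimSection)
    design: DesignSection = field(default_factory=DesignSection)
    population: PopulationSection = field(default_factory=PopulationSection)
    sampler: SamplerSection = field(default_factory=SamplerSection)

    _REQUIRED_WHEN_PRESENT = {"arena": ("diameter",), "sim": ("duration", "dt")}
    _SECTIONS = {
        "arena": ArenaConfig,
        "sim": SimSection,
        "design": DesignSection,
        "population": PopulationSection,
        "sampler": SamplerSection,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw.pop("seed"))
        for name, section_cls in cls._SECTIONS.items():
            if name not in raw:
                continue
            section = raw.pop(name)
            if not isinstance(section, dict):
                raise SchemaError(f"section '{name}' must be a mapping")
            for req in cls._REQUIRED_WHEN_PRESENT.get(name, ()):
                if section.get(req) is None:
                    raise SchemaError(f"missing required field '{name}.{req}'")
            valid = {f for f in section_cls.__dataclass_fields__}
            unknown = set(section) - valid
            if unknown:
                raise SchemaError(f"unknown field '{name}.{sorted(unknown)[0]}'")
            kwargs[name] = section_cls(**section)
        if raw:
            raise SchemaError(f"unknown section '{sorted(raw)[0]}'")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _stage_seeds(root_seed: int, n: int = 8) -> list[int]:
    """Integer per-stage seeds derived from the root seed (all < 2^31)."""
    state = np.random.SeedSequence(root_seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(type(obj))


def run_end_to_end(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic pipeline and write a report bundle.

    Stages: fit a motion model to fish-like trajectories simulated from
    the reference law; simulate ballistic and fish-like stimuli; build
    the two experimental designs; simulate observers and their
    responses; fit the hierarchical SDT model and summarise recovery.
    Outputs (trajectory/design/response CSVs, report.json) are
    deterministic for a fixed config, byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    arena = stimuli.ArenaSpec(
        center=tuple(config.arena.center),
        diameter=config.arena.diameter,
        scene_extent=tuple(config.arena.scene_extent),
    )
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage=%s config=%s", name, config.config_hash())

    try:
        stage("motion_fit")
        true_model = default_motion_model()
        fit_cfg = stimuli.SimConfig(
            n_objects=5,
            duration=60.0,
            dt=config.sim.dt,
            object_radius=config.sim.object_radius,
            seed=seeds[0],
        )
        fish_trajs = stimuli.simulate_fishlike(arena, true_model, fit_cfg)
        # radius sized to the synthetic jitter (3 px), not the 60 px used
        # for real fish whose positional jitter is far larger; a dash
        # slower than radius/min_wait would otherwise count as waiting
        fitted = motion.fit_motion_model(fish_trajs, radius_px=5.0, min_wait_s=0.3)
        report["stages"]["motion_fit"] = {
            "wait_k": fitted.wait_duration.k,
            "wait_theta": fitted.wait_duration.theta,
            "dash_distance_k": fitted.dash_distance.k,
            "dash_distance_theta": fitted.dash_distance.theta,
            "dash_velocity_k": fitted.dash_velocity.k,
            "dash_velocity_theta": fitted.dash_velocity.theta,
        }

        stage("stimuli")
        sim_cfg = stimuli.SimConfig(
            n_objects=config.sim.n_objects,
            duration=config.sim.duration,
            dt=config.sim.dt,
            speed=config.sim.speed,
            object_radius=config.sim.object_radius,
            seed=seeds[1],
        )
        ballistic = stimuli.simulate_ballistic(arena, sim_cfg, return_events=True)
        write_trajectories_csv(ballistic.trajectories, out / "trajectories_ballistic.csv")
        fishlike = stimuli.simulate_fishlike(arena, true_model, sim_cfg)
        write_trajectories_csv(fishlike, out / "trajectories_fishlike.csv")
        check = stimuli.replay_check_ballistic(ballistic, arena, sim_cfg)
        report["stages"]["stimuli"] = check

        stage("design")
        videos = [f"v{i:02d}" for i in range(config.design.n_videos)]
        exp1 = design_mod.build_design_exp1(
            videos,
            set_sizes=list(config.design.set_sizes),
            n_objects=config.design.n_objects,
            seed=seeds[2],
        )
        design_mod.write_design_csv(exp1, out / "design_exp1.csv")
        report["stages"]["design"] = {
            "exp1_trials": len(exp1),
            "target_query_fraction": float(
                np.mean([t.queried_is_target for t in exp1])
            ),
        }

        stage("observers")
        pop = observer.PopulationParams(
            alpha_d=config.population.alpha_d,
            beta_d=config.population.beta_d,
            alpha_c=config.population.alpha_c,
            beta_c=config.population.beta_c,
            sigma_ad=config.population.sigma_ad,
            sigma_bd=config.population.sigma_bd,
            sigma_ac=config.population.sigma_ac,
            sigma_bc=config.population.sigma_bc,
        )
        observers = observer.sample_observers(pop, config.population.n_participants, seed=seeds[3])
        responses = observer.simulate_responses(observers, exp1, pop, seed=seeds[4])
        responses.to_csv(out / "responses.csv", index=False)
        report["stages"]["observers"] = {
            "n_participants": len(observers),
            "n_responses": len(responses),
            "accuracy": float(responses["correct"].mean()),
        }

        stage("sdt_fit")
        post = inference.fit_sdt_probit(
            responses,
            prior_sd=config.sampler.prior_sd,
            n_chains=config.sampler.n_chains,
            warmup=config.sampler.warmup,
            draws=config.sampler.draws,
            seed=seeds[5],
        )
        summary = inference.summarize_dprime_bias(post, at_loads=list(config.design.set_sizes))
        summary.to_csv(out / "sdt_summary.csv", index=False)
        report["stages"]["sdt_fit"] = {
            "d_intercept_mean": float(np.mean(post.draws("d_intercept"))),
            "d_load_mean": float(np.mean(post.draws("d_load"))),
            "c_intercept_mean": float(np.mean(post.draws("c_intercept"))),
            "c_load_mean": float(np.mean(post.draws("c_load"))),
            "true": {
                "d_intercept": pop.alpha_d,
                "d_load": pop.beta_d,
                "c_intercept": pop.alpha_c,
                "c_load": pop.beta_c,
            },
        }
    except Exception as exc:  # preserve partial outputs, name the stage
        failed = list(report["stages"])
        report["error"] = {"after_stages": failed, "message": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the small bundled datasets the test suite exercises:
    a 3-object 10 s fish-like trajectory file, a 12-trial design, and
    a 4-participant response table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    arena = stimuli.ArenaSpec()
    cfg = stimuli.SimConfig(n_objects=3, duration=10.0, seed=seeds[0])
    trajs = stimuli.simulate_fishlike(arena, default_motion_model(), cfg)
    traj_path = out / "fixture_trajectories.csv"
    write_trajectories_csv(trajs, traj_path)

    videos = ["v0", "v1", "v2"]
    trials = design_mod.build_design_exp1(videos, set_sizes=[1, 3], n_objects=8, seed=seeds[1])
    design_path = out / "fixture_design.csv"
    design_mod.write_design_csv(trials, design_path)

    pop = observer.PopulationParams()
    observers = observer.sample_observers(pop, 4, seed=seeds[2])
    responses = observer.simulate_responses(observers, trials, pop, seed=seeds[3])
    resp_path = out / "fixture_responses.csv"
    responses.to_csv(resp_path, index=False)
    return {"trajectories": traj_path, "design": design_path, "responses": resp_path}
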