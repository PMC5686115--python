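"""Pipeline orchestration: declarative configuration, stage sequencing,
logging and standard-format output.

A run executes simulate → detect → track → classify on a synthetic TIRF
scene and, as requested, the FRAP, bleach-step, Ca2+-puff and STIM1-
junction stages, writing CSV tables, a summary JSON and a run log
recording the seed and every parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import frap as frap_mod
from . import junctions as junc_mod
from . import mobility as mob_mod
from . import puffs as puff_mod
from . import simulate as sim_mod
from . import stoichiometry as stoi_mod
from . import tracking as track_mod
from .detection import detect_spots_movie
from .io import write_movie, write_table

log = logging.getLogger("punctakit")


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Unknown keys are rejected at load time so silent typos cannot change
    an analysis.
    """

    seed: int = 0
    stages: tuple = ("simulate", "detect", "track", "classify")
    scene: dict = field(default_factory=dict)
    detection: dict = field(default_factory=lambda: {"threshold_sd": 5.0})
    linking: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    frap: dict = field(
        default_factory=lambda: {
            "mf": 0.77,
            "t_half_s": 62.0,
            "r_um": 1.84,
            "gamma": 1.0,
        }
    )
    bleach: dict = field(
        default_factory=lambda: {"n_traces": 50, "mean_fluorophores": 16.4}
    )
    puffs: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)
    units: dict = field(default_factory=lambda: {"length": "um", "time": "s"})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages, writing all outputs under ``outdir``.

    Returns the summary dictionary (also written as summary.json). A stage
    failure aborts the run with the failing stage named; outputs written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    state: dict = {}
    run_log = {
        "punctakit_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        try:
            fn(config, state, summary, outdir)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_jsonify)
    )
    return summary


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, state, summary, outdir):
    params = dict(config.scene)
    intensity = params.pop("intensity", 400.0)
    scene = sim_mod.SceneConfig(seed=config.seed, **params)
    observed, truth = sim_mod.simulate_trajectories(scene)
    movie = sim_mod.render_movie(observed, scene, intensities=intensity)
    state.update(scene=scene, observed=observed, truth=truth, movie=movie)
    write_movie(movie, outdir / "movie.tif")
    write_table(truth.puncta, outdir / "ground_truth_puncta.csv")
    summary["n_puncta_simulated"] = int(scene.n_puncta)


def _stage_detect(config, state, summary, outdir):
    movie = state["movie"]
    scene = state["scene"]
    spots = detect_spots_movie(
        movie, scene.psf_sigma_um, config.detection.get("threshold_sd", 5.0)
    )
    state["spots"] = spots
    write_table(spots, outdir / "spots.csv")
    summary["n_spots"] = int(len(spots))


def _stage_track(config, state, summary, outdir):
    cfg = track_mod.LinkingConfig(**config.linking)
    tracks, track_summary = track_mod.track(state["spots"], cfg)
    state.update(tracks=tracks, track_summary=track_summary, linking=cfg)
    write_table(tracks, outdir / "tracks.csv")
    write_table(track_summary, outdir / "track_summary.csv")
    summary["n_tracks"] = int(track_summary["kept"].sum())


def _stage_classify(config, state, summary, outdir):
    scene = state["scene"]
    cls_cfg = mob_mod.ClassifierConfig(**config.classifier)
    classes = mob_mod.classify_tracks(
        state["tracks"], scene.frame_interval_s, cls_cfg
    )
    state["classes"] = classes
    write_table(classes, outdir / "track_classes.csv")
    if len(classes):
        stats = mob_mod.mobility_summary([classes["label"].tolist()])
        summary["state_fractions"] = {
            lab: stats["pooled"][lab]["mean"] for lab in mob_mod.MOBILITY_LABELS
        }
        directed = classes[classes["label"] == "directed"]
        if len(directed):
            summary["directed_speed_um_s"] = float(directed["v_um_s"].mean())
        diffusive = classes[classes["label"] == "diffusive"]
        if len(diffusive):
            summary["diffusion_coefficient_um2_s"] = float(
                diffusive["D_um2_s"].mean()
            )


def _stage_frap(config, state, summary, outdir):
    p = dict(config.frap)
    r_um = p.pop("r_um", 1.84)
    gamma = p.pop("gamma", 1.0)
    sim = sim_mod.simulate_frap_curve(seed=config.seed, **p)
    report = frap_mod.analyze_frap(
        sim.roi,
        sim.cell,
        sim.bleach_frame,
        float(sim.time_s[1] - sim.time_s[0]),
        r_um=r_um,
        gamma=gamma,
    )
    curve = report.pop("curve")
    write_table(
        pd.DataFrame({"time_s": curve.time_s, "normalized": curve.normalized}),
        outdir / "frap_curve.csv",
    )
    summary["frap"] = report


def _stage_bleach(config, state, summary, outdir):
    p = config.bleach
    rng = np.random.default_rng(config.seed + 7)
    n_traces = p.get("n_traces", 50)
    mean_n = p.get("mean_fluorophores", 16.4)
    rows = []
    for i in range(n_traces):
        n_true = max(1, int(rng.poisson(mean_n)))
        trace = sim_mod.simulate_bleach_trace(
            n_true, noise_sd=p.get("noise_sd", 10.0), seed=int(rng.integers(2**31))
        )
        rep = stoi_mod.analyze_bleach_trace(trace.intensity, trace.frame_interval_s)
        rows.append(
            {
                "trace": i,
                "true_n": n_true,
                "F0": rep["F0"],
                "final_step": rep["final_step"],
                "n_fluorophores": rep["n_fluorophores"],
                "n_tetramers": rep["n_tetramers"],
            }
        )
    table = pd.DataFrame(rows)
    write_table(table, outdir / "bleach_stoichiometry.csv")
    summary["bleach"] = {
        "n_traces": int(n_traces),
        "mean_tetramers_per_punctum": float(table["n_tetramers"].mean()),
        "prob_tagged_tetramer": stoi_mod.prob_tagged_tetramer(),
        "prob_fluorescent_tetramer": stoi_mod.prob_tagged_tetramer(
            require_fluorescent=True
        ),
    }


def _stage_puffs(config, state, summary, outdir):
    p = dict(config.puffs)
    scene = state.get("scene") or sim_mod.SceneConfig(seed=config.seed)
    ca_scene = scene.with_(
        frame_interval_s=p.pop("frame_interval_s", 0.05),
        n_frames=p.pop("n_frames", 600),
    )
    truth = state.get("truth")
    if truth is not None:
        imm = truth.puncta[truth.puncta["kind"] == "immobile"]
        immobile = truth.true_positions[imm.index.to_numpy(), 0, :]
    else:
        rng = np.random.default_rng(config.seed + 11)
        w, h = ca_scene.field_size_um
        immobile = np.column_stack(
            [rng.uniform(1, w - 1, 20), rng.uniform(1, h - 1, 20)]
        )
    movie, puff_truth = sim_mod.simulate_puff_scene(
        ca_scene, immobile, seed=config.seed + 13, **p
    )
    dff = puff_mod.compute_dff(movie, baseline_frames=10)
    events = puff_mod.detect_puffs(dff)
    events, assign = puff_mod.assign_puffs_to_puncta(events, immobile)
    sites = puff_mod.site_recurrence(events)
    write_table(events, outdir / "puff_events.csv")
    write_table(sites, outdir / "puff_sites.csv")
    write_table(puff_truth.puffs, outdir / "ground_truth_puffs.csv")
    summary["puffs"] = {**assign, "n_sites": int(len(sites))}


def _stage_junctions(config, state, summary, outdir):
    p = dict(config.junctions)
    scene = state.get("scene") or sim_mod.SceneConfig(seed=config.seed)
    truth = state.get("truth")
    if truth is not None:
        imm_idx = truth.puncta.index[truth.puncta["kind"] == "immobile"].to_numpy()
        mob_idx = truth.puncta.index[truth.puncta["kind"] != "immobile"].to_numpy()
        immobile = truth.true_positions[imm_idx, 0, :]
        mobile = truth.true_positions[mob_idx, 0, :]
    else:
        rng = np.random.default_rng(config.seed + 17)
        w, h = scene.field_size_um
        immobile = np.column_stack([rng.uniform(1, w - 1, 30), rng.uniform(1, h - 1, 30)])
        mobile = np.column_stack([rng.uniform(1, w - 1, 70), rng.uniform(1, h - 1, 70)])
    stim, _ = sim_mod.simulate_stim1_field(
        immobile, mobile, scene.field_size_um, seed=config.seed + 19, **p
    )
    d = junc_mod.nn_distances(immobile, stim)
    frac_2r, _ = junc_mod.fraction_within(immobile, stim, radius_um=0.8)
    frac_300, _ = junc_mod.fraction_within(immobile, stim, radius_um=0.3)
    write_table(
        pd.DataFrame({"nn_distance_um": d}), outdir / "junction_nn_distances.csv"
    )
    summary["junctions"] = {
        **junc_mod.nn_summary(d),
        "fraction_within_2r": frac_2r,
        "fraction_within_300nm": frac_300,
        "stim_density_per_um2": stim.intensity,
    }


_STAGES = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "track": _stage_track,
    "classify": _stage_classify,
    "frap": _stage_frap,
    "bleach": _stage_bleach,
    "puffs": _stage_puffs,
    "junctions": _stage_junctions,
}
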