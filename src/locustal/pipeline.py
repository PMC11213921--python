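"""End-to-end orchestration of the behavior and imaging analysis arms.

``run_pipeline`` executes the module chain in a fixed order from a single
validated configuration and writes a report directory of tables and JSON
summaries.  All randomness is threaded from the config seed; rerunning an
identical config reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, io, motifs, preproc, responses, segmentation, synergy
from .choice_model import PATCHES, fit_reliability
from .synthetic import (AgentSpec, SceneSpec, generate_calcium_movies,
                        generate_choice_trajectories,
                        quarter_occupancy_from_trajectories)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

MODES = ("behavior", "imaging", "synthetic-demo")


@dataclass
class RunConfig:
    """Validated pipeline configuration (schema version 1)."""

    mode: str = "synthetic-demo"
    out_dir: str = "locustal_report"
    seed: int = 0
    # inputs (behavior / imaging modes)
    trajectory_csv: str | None = None
    patch_config_json: str | None = None
    movie_tiffs: list = field(default_factory=list)
    fps: float = 25.0
    # analysis parameters
    analysis_window: int = 10           # frames after onset
    k_min: int = 2
    k_max: int = 20
    var_vectors: float = 0.99
    var_consistency: float = 0.95
    var_classifier: float = 0.83
    n_repeats: int = 100                # reliability-fit repetitions
    kmeans_replicates: int = 50
    B: int = 100_000                    # randomization resamples
    n_boot: int = 5000
    # synthetic-demo sizes
    demo_agents: int = 20
    demo_frames: int = 4000
    demo_cells: int = 12
    schema_version: int = 1

    def validate(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name in ("var_vectors", "var_consistency", "var_classifier"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("invalid k range")
        if self.mode == "behavior" and not self.trajectory_csv:
            raise ValueError("behavior mode needs trajectory_csv")
        if self.mode == "imaging" and not self.movie_tiffs:
            raise ValueError("imaging mode needs movie_tiffs")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**data).validate()


def _behavior_arm(cfg: RunConfig, out: Path, trajs_by_cond, patch_quadrants,
                  rng, W_set=None):
    occ, frames = {}, []
    for cond, trajs in trajs_by_cond.items():
        trajs = [behavior.smooth_trajectory(t) for t in trajs]
        occ[cond] = quarter_occupancy_from_trajectories(trajs, patch_quadrants)
        df = pd.DataFrame(occ[cond], columns=list(PATCHES))
        df.insert(0, "animal", [t.animal_id for t in trajs])
        df.insert(0, "condition", cond)
        frames.append(df)
    occ_df = pd.concat(frames, ignore_index=True)
    occ_df.to_csv(out / "occupancy.csv", index=False)

    est = fit_reliability(occ, W_set, n_repeats=cfg.n_repeats,
                          seed=int(rng.integers(2 ** 31)))
    io.write_json(est.as_dict(), out / "reliability.json")
    return {"occupancy": occ_df, "reliability": est}


def _imaging_arm(cfg: RunConfig, out: Path, movies):
    dffs, infos = [], {}
    for m in movies:
        dff, info = preproc.preprocess(m, window_frames=cfg.analysis_window)
        dffs.append(dff)
        infos[m.stimulus] = {"bleach_slope": info["bleach_slope"],
                             "max_shift": float(np.abs(info["shifts"]).max())}
    gmap, resp = segmentation.segment_and_quantify(dffs)
    io.write_label_map(gmap.labels, out / "granule_labels.tif")
    gmap.table().to_csv(out / "granules.csv", index=False)
    resp.to_csv(out / "responses.csv", index=False)

    # motif analysis over max-seeded granules with all three stimuli
    stimuli = tuple(d.stimulus for d in dffs)
    use_stims = motifs.DEFAULT_STIMULI if set(motifs.DEFAULT_STIMULI) <= set(stimuli) \
        else stimuli
    max_granules = [g for g in gmap.ids
                    if gmap.seed_type.get(int(g), "max") == "max"]
    rows, unit, stim = [], [], []
    traces_by_stim = {d.stimulus: segmentation.granule_traces(gmap, d) for d in dffs}
    for g in max_granules:
        for s in use_stims:
            rows.append(traces_by_stim[s][int(g)])
            unit.append(int(g))
            stim.append(s)
    prof = motifs.build_profile_matrix(np.array(rows), unit, stim,
                                       animal=["a0"] * len(unit))
    k_max = min(cfg.k_max, len(rows) - 1)
    mset = motifs.cluster_motifs(prof, k_range=range(cfg.k_min, k_max + 1),
                                 n_replicates=cfg.kmeans_replicates,
                                 variance_retained=cfg.var_vectors)
    trips = motifs.motif_triplets(mset, stimuli=use_stims)
    trips.to_csv(out / "triplets.csv")

    result = {"gmap": gmap, "responses": resp, "motifs": mset, "triplets": trips}
    if set(motifs.DEFAULT_STIMULI) <= set(stimuli):
        window = dffs[0].window
        trip_lookup = {u: tuple(trips.loc[u, list(motifs.DEFAULT_STIMULI)])
                       for u in trips.index}
        unit_traces = {
            int(g): (traces_by_stim["Laa"][int(g)], traces_by_stim["Lct"][int(g)],
                     traces_by_stim["LaaLct"][int(g)])
            for g in trips.index
        }
        btraces = synergy.bliss_traces(unit_traces, window, trip_lookup)
        pooled = [b.summary for b in btraces if b.pooled]
        if len(pooled) >= 2:
            frac = synergy.synergistic_fraction(pooled)
            io.write_json(frac, out / "synergy.json")
            result["synergy"] = frac
        result["bliss"] = btraces
    io.write_json(infos, out / "preproc_log.json")
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis arms and write the report bundle.

    Returns a dict of in-memory results keyed by arm.  The report directory
    holds the occupancy and response tables, label map, fitted reliability
    scores, synergy summary and a run log (parameters + seed).
    """
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    results = {}

    if cfg.mode in ("behavior", "synthetic-demo"):
        if cfg.mode == "behavior":
            trajs = behavior.read_trajectories_csv(cfg.trajectory_csv, fps=cfg.fps)
            patch_cfg = io.read_json(cfg.patch_config_json)
            quad = behavior.patch_quadrants_from_centers(
                {k: tuple(v) for k, v in patch_cfg["patch_centers"].items()},
                tuple(patch_cfg.get("arena_center", (0.0, 0.0))))
            trajs_by_cond = {patch_cfg.get("condition", "Vis+Olf+"): trajs}
            results["behavior"] = _behavior_arm(cfg, out, trajs_by_cond, quad, rng)
        else:
            # emulate the full assay: one agent cohort per sensory condition
            from .choice_model import default_availability

            W_set = default_availability()
            true_C = np.array([10.0, 1.0, 1.0, 1.0])
            trajs_by_cond = {}
            for cond, W in W_set.items():
                spec = AgentSpec(n_agents=cfg.demo_agents,
                                 n_frames=cfg.demo_frames, true_C=true_C,
                                 W=W, seed=int(rng.integers(2 ** 31)))
                trajs_by_cond[cond], truth = generate_choice_trajectories(spec)
            quad = {p: i for i, p in enumerate(PATCHES)}
            results["behavior_truth"] = {"true_C": true_C}
            results["behavior"] = _behavior_arm(cfg, out, trajs_by_cond, quad,
                                                rng, W_set)

    if cfg.mode in ("imaging", "synthetic-demo"):
        if cfg.mode == "imaging":
            movies = [io.read_movie(p) for p in cfg.movie_tiffs]
        else:
            scene = SceneSpec(n_cells=cfg.demo_cells,
                              seed=int(rng.integers(2 ** 31)))
            movies, truth = generate_calcium_movies(scene)
            results["imaging_truth"] = truth
        results["imaging"] = _imaging_arm(cfg, out, movies)

    io.write_json({"config": asdict(cfg)}, out / "run_log.json")
    return results
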