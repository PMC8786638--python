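"""Table formats, configuration, schedule arithmetic and run manifests.

The pipeline's interchange dialect is a comma-separated trajectory table
with one row per frame x agent and columns

    trial_id, frame, t_s, agent_id, species, x_cm, y_cm, heading_rad[, source]

(units embedded in the column names; UTF-8; newline-terminated), plus a
sidecar attack-log table and a YAML config snapshot.  Both the simulator's
ground-truth recordings and the tracker's reconstructions are written in
this dialect, so the metrics stage is source-agnostic.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .arena import (
    ArenaGeometry,
    AttackEvent,
    CouplingSpec,
    Species,
    Tier,
    TrialRecording,
)
from .tracking import Track, TrackSet

__all__ = [
    "ExperimentPlan",
    "RunManifest",
    "TrajectoryParseError",
    "enumerate_schedule",
    "write_trajectories",
    "read_trajectories",
    "write_attacks",
    "read_attacks",
    "write_trackset",
    "read_trackset",
    "write_frames",
    "read_frames",
    "load_config",
    "default_config",
    "stage_seed",
]

TRAJ_COLUMNS = ["trial_id", "frame", "t_s", "agent_id", "species",
                "x_cm", "y_cm", "heading_rad"]
ATTACK_COLUMNS = ["t_trigger_s", "target_id", "initial_distance_cm",
                  "tier", "t_complete_s"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory table; carries the offending row index when
    known."""


# --------------------------------------------------------------------------
# Experiment schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentPlan:
    """Counts defining the experimental design.

    Defaults mirror a 12-tank mesocosm study assayed in the arena twice a
    week for seven weeks, with home-tank observations twice a day on four
    days a week.
    """

    n_tanks: int = 12
    groups_per_treatment: int = 6
    arena_assays_per_week: int = 2
    weeks: int = 7
    home_assays_per_day: int = 2
    home_days_per_week: int = 4

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


def enumerate_schedule(plan: ExperimentPlan = ExperimentPlan()):
    """Total trial counts implied by a design.

    Returns ``(arena_trials_total, arena_trials_per_group,
    home_trials_total)``; with the default plan: 168, 14 and 672.
    """
    per_group = plan.arena_assays_per_week * plan.weeks
    arena_total = per_group * plan.n_tanks
    home_total = (
        plan.n_tanks * plan.home_assays_per_day
        * plan.home_days_per_week * plan.weeks
    )
    return arena_total, per_group, home_total


# --------------------------------------------------------------------------
# Trajectory tables
# --------------------------------------------------------------------------


def _recording_frame(recording: TrialRecording, trial_id: str) -> pd.DataFrame:
    n_f, n_a = recording.n_frames, recording.n_agents
    frames = np.repeat(np.arange(n_f), n_a)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "frame": frames,
            "t_s": frames / recording.fps,
            "agent_id": np.tile(np.array(recording.agent_ids, dtype=object), n_f),
            "species": np.tile(
                np.array([s.value for s in recording.species], dtype=object), n_f
            ),
            "x_cm": recording.positions[:, :, 0].ravel(),
            "y_cm": recording.positions[:, :, 1].ravel(),
            "heading_rad": recording.headings.ravel(),
        }
    )


def write_trajectories(recording: TrialRecording, path, trial_id: str = "trial") -> None:
    """Write a TrialRecording as the delimited trajectory dialect, with the
    attack log and a config snapshot alongside (.attacks.csv / .config.yaml)."""
    path = Path(path)
    _recording_frame(recording, trial_id).to_csv(path, index=False, lineterminator="\n")
    write_attacks(recording.attacks, path.with_suffix(".attacks.csv"))
    snapshot = {
        "trial_id": trial_id,
        "fps": recording.fps,
        "duration_s": recording.duration,
        "treatment": recording.treatment,
        "seed": recording.seed,
        "coupling": asdict(recording.coupling),
        "arena": asdict(recording.geometry),
    }
    path.with_suffix(".config.yaml").write_text(
        yaml.safe_dump(snapshot, sort_keys=True), encoding="utf-8"
    )


def read_trajectories(path) -> TrialRecording:
    """Read a trajectory table (and sidecars, if present) back into a
    TrialRecording; exact round trip of all trajectory fields."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TrajectoryParseError(f"empty or missing trajectory file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"missing columns {missing} in {path}")
    if len(df) == 0:
        raise TrajectoryParseError(f"no rows in {path}")

    dup = df.duplicated(subset=["frame", "agent_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.values)[0])
        raise TrajectoryParseError(f"duplicated (frame, agent_id) at row {row}")
    frames_seen = df["frame"].to_numpy()
    if np.any(np.diff(frames_seen) < 0):
        row = int(np.flatnonzero(np.diff(frames_seen) < 0)[0] + 1)
        raise TrajectoryParseError(f"non-monotone frame index at row {row}")

    agent_ids = list(df.loc[df["frame"] == 0, "agent_id"])
    species = [Species(s) for s in df.loc[df["frame"] == 0, "species"]]
    n_a = len(agent_ids)
    n_f = int(df["frame"].max()) + 1
    if len(df) != n_a * n_f:
        raise TrajectoryParseError(
            f"expected {n_a * n_f} rows for {n_a} agents x {n_f} frames, got {len(df)}"
        )
    pos = np.empty((n_f, n_a, 2))
    pos[:, :, 0] = df["x_cm"].to_numpy().reshape(n_f, n_a)
    pos[:, :, 1] = df["y_cm"].to_numpy().reshape(n_f, n_a)
    headings = df["heading_rad"].to_numpy().reshape(n_f, n_a)

    fps, duration, treatment, seed = 20.0, n_f / 20.0, "non_exposed", 0
    coupling, geometry = CouplingSpec(), ArenaGeometry()
    cfg_path = path.with_suffix(".config.yaml")
    if cfg_path.exists():
        snap = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
        fps = float(snap["fps"])
        duration = float(snap["duration_s"])
        treatment = snap["treatment"]
        seed = int(snap["seed"])
        coupling = CouplingSpec(**snap["coupling"])
        geometry = ArenaGeometry(**snap["arena"])
    attacks = []
    att_path = path.with_suffix(".attacks.csv")
    if att_path.exists():
        attacks = read_attacks(att_path)
    return TrialRecording(
        fps=fps, duration=duration, agent_ids=agent_ids, species=species,
        positions=pos, headings=headings, attacks=attacks,
        treatment=treatment, seed=seed, coupling=coupling, geometry=geometry,
    )


def write_attacks(attacks, path) -> None:
    pd.DataFrame(
        [
            {
                "t_trigger_s": a.t_trigger,
                "target_id": a.target_id,
                "initial_distance_cm": a.initial_distance,
                "tier": a.tier.value,
                "t_complete_s": a.t_complete,
            }
            for a in attacks
        ],
        columns=ATTACK_COLUMNS,
    ).to_csv(path, index=False, lineterminator="\n")


def read_attacks(path) -> list:
    df = pd.read_csv(path)
    return [
        AttackEvent(
            t_trigger=float(r.t_trigger_s),
            target_id=str(r.target_id),
            initial_distance=float(r.initial_distance_cm),
            tier=Tier(r.tier),
            t_complete=float(r.t_complete_s),
        )
        for r in df.itertuples()
    ]


def write_trackset(ts: TrackSet, path, trial_id: str = "trial") -> None:
    """Write tracker output in the trajectory dialect plus a source column."""
    rows = []
    for tr in ts.tracks:
        for k, (t, p, src) in enumerate(zip(tr.times, tr.positions, tr.sources)):
            rows.append(
                (trial_id, k, t, tr.agent_id, tr.species.value,
                 p[0], p[1], float("nan"), src)
            )
    df = pd.DataFrame(rows, columns=TRAJ_COLUMNS + ["source"])
    df.sort_values(["frame", "agent_id"], inplace=True, kind="stable")
    df.to_csv(path, index=False, lineterminator="\n")


def read_trackset(path, fps: float = 20.0,
                  geometry: ArenaGeometry = ArenaGeometry(),
                  cm_per_pixel: float = 0.1) -> TrackSet:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TrajectoryParseError(f"empty or missing trackset file: {path}")
    df = pd.read_csv(path)
    need = TRAJ_COLUMNS + ["source"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"missing columns {missing} in {path}")
    tracks = []
    for aid, sub in df.groupby("agent_id", sort=False):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                agent_id=str(aid),
                species=Species(sub["species"].iloc[0]),
                times=list(sub["t_s"].astype(float)),
                positions=[np.array([x, y]) for x, y in zip(sub["x_cm"], sub["y_cm"])],
                sources=list(sub["source"]),
            )
        )
    return TrackSet(tracks=tracks, fps=fps, geometry=geometry,
                    cm_per_pixel=cm_per_pixel)


# --------------------------------------------------------------------------
# Image stacks
# --------------------------------------------------------------------------


def write_frames(frames: np.ndarray, path) -> None:
    """Write a grayscale frame stack as a multi-page TIFF (or a directory of
    PNGs if ``path`` has no .tif/.tiff suffix)."""
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, np.asarray(frames))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", fr)


def read_frames(path) -> np.ndarray:
    """Read a stack written by :func:`write_frames`; RGB input is converted
    to grayscale by the standard luma weights."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        stack = np.stack([iio.imread(f) for f in files])
    else:
        stack = np.asarray(iio.imread(path))
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim == 4:  # RGB(A)
        stack = (
            0.2126 * stack[..., 0] + 0.7152 * stack[..., 1] + 0.0722 * stack[..., 2]
        ).astype(np.uint8)
    return stack


# --------------------------------------------------------------------------
# Config and manifests
# --------------------------------------------------------------------------


def default_config() -> dict:
    """Default pipeline configuration, with per-stage sections and one
    global seed from which stage seeds are derived."""
    return {
        "seed": 0,
        "arena": asdict(ArenaGeometry()),
        "agents": {"n_fish": 6, "n_tadpoles": 6},
        "coupling": asdict(CouplingSpec()),
        "robot": {
            "treatment": "robot_exposed",
            "attack_rate_per_min": 1.0,
            "standardize_attacks": None,
        },
        "trial": {"duration_s": 3600.0, "fps": 20.0},
        "render": {
            "image_size": [480, 480],
            "cm_per_pixel": 0.1,
            "noise_sd": 3.0,
            "miss_rate": 0.0,
        },
        "te": {"dt_s": 0.5, "n_perm": 20000},
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed; always
    below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Provenance record binding a stage's outputs to its config and seeds."""

    stage: str
    config_hash: str
    seeds: dict
    inputs: list
    outputs: list
    timestamp: str
    version: str = "0.1.0"

    @classmethod
    def create(cls, stage: str, config: dict, seeds: dict,
               inputs: list, outputs: list) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            stage=stage,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seeds=seeds,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n",
                              encoding="utf-8")
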