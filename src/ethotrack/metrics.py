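"""Per-trial group-behaviour measures and the Fulton condition factor.

Cohesion (average furthest-neighbour distance and average inter-individual
distance), activity (distance swam, unsigned turning rate), and space use
(time in concentric arena regions) are computed frame-wise and then averaged
over the trial, per species.  All distances are in cm, times in s, turning
rates in rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arena import ArenaGeometry, Species

__all__ = [
    "BehaviorSummary",
    "MorphRecord",
    "UndefinedMetricError",
    "MOTION_FLOOR_CM",
    "afnd",
    "aiid",
    "distance_swam",
    "turning_rate",
    "turning_angles",
    "region_occupancy",
    "fulton_k",
    "summarize_species",
]

#: Minimum per-step displacement (cm) for a turning angle to be defined;
#: below it the step is skipped so sensor noise at rest cannot masquerade
#: as turning.
MOTION_FLOOR_CM = 0.1


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (enough individuals / motion)
    are not met."""


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-trial, per-species behavioural metric vector."""

    trial_id: str
    species: str
    afnd: float
    aiid: float
    distance_swam: float
    turning_rate: float
    central_time: float
    external_time: float
    per_ring_time: tuple

    def __post_init__(self) -> None:
        if self.aiid > self.afnd + 1e-9:
            raise ValueError("AIID cannot exceed AFND")


@dataclass(frozen=True)
class MorphRecord:
    """One morphometric measurement of an individual fish."""

    individual_id: str
    sex: str
    standard_length_mm: float
    weight_g: float

    @property
    def k_factor(self) -> float:
        return fulton_k(self.weight_g, self.standard_length_mm)


def _positions_3d(positions) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    if p.ndim == 2:
        p = p[None, ...]
    if p.ndim != 3 or p.shape[-1] != 2:
        raise ValueError("positions must have shape (n_frames, n_individuals, 2)")
    return p


def _pairwise(p: np.ndarray) -> np.ndarray:
    return np.linalg.norm(p[:, :, None, :] - p[:, None, :, :], axis=-1)


def afnd(positions) -> float:
    """Average furthest-neighbour distance.

    Per frame, each individual's distance to its most distant group-mate is
    averaged over individuals; the trial value is the mean over frames.
    """
    p = _positions_3d(positions)
    if p.shape[1] < 2:
        raise UndefinedMetricError("AFND needs at least two individuals")
    return float(_pairwise(p).max(axis=2).mean())


def aiid(positions) -> float:
    """Average inter-individual distance: mean over all C(n,2) pairs per
    frame, then mean over frames."""
    p = _positions_3d(positions)
    n = p.shape[1]
    if n < 2:
        raise UndefinedMetricError("AIID needs at least two individuals")
    d = _pairwise(p)
    iu = np.triu_indices(n, k=1)
    return float(d[:, iu[0], iu[1]].mean())


def distance_swam(positions) -> float:
    """Total path length per individual, averaged over the group.

    ``positions`` may be (n_frames, 2) for one individual or
    (n_frames, n_individuals, 2) for a group.
    """
    p = np.asarray(positions, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[:, None, :]
    if p.shape[0] < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(p, axis=0), axis=-1)
    totals = steps.sum(axis=0)
    return float(totals[0] if single else totals.mean())


def turning_angles(positions, motion_floor: float = MOTION_FLOOR_CM):
    """Unsigned angles between successive displacement vectors of one track.

    Returns ``(angles, valid)`` arrays of length n_frames-2; ``valid`` is
    False where either displacement is below the motion floor (heading is
    undefined at rest).
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or len(p) < 3:
        raise UndefinedMetricError("turning angles need >=3 samples of one track")
    d = np.diff(p, axis=0)
    norms = np.linalg.norm(d, axis=1)
    valid = (norms[:-1] >= motion_floor) & (norms[1:] >= motion_floor)
    cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
    dot = (d[:-1] * d[1:]).sum(axis=1)
    angles = np.abs(np.arctan2(cross, dot))
    return angles, valid


def turning_rate(positions, dt: float, motion_floor: float = MOTION_FLOOR_CM) -> float:
    """Average unsigned turning rate in rad/s.

    Per step, the angle between successive displacement vectors divided by
    ``dt``; steps where either displacement is below the motion floor are
    skipped.  For a group array the per-individual means are averaged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = np.asarray(positions, dtype=float)
    if p.ndim == 2:
        angles, valid = turning_angles(p, motion_floor)
        if not valid.any():
            raise UndefinedMetricError("no step above the motion floor")
        return float(angles[valid].mean() / dt)
    rates = [turning_rate(p[:, i, :], dt, motion_floor) for i in range(p.shape[1])]
    return float(np.mean(rates))


def region_occupancy(
    positions,
    geometry: ArenaGeometry = ArenaGeometry(),
    fps: float = 20.0,
):
    """Time spent in the central/external regions and each concentric ring.

    Samples are binned into rings of width ``geometry.ring_width`` by
    ``floor(r / width)`` (half-open rings; the outermost ring includes the
    wall).  Rings within ``central_radius`` form the central region, the
    rest the external region.  For group arrays, per-individual times are
    averaged.  Times are sample counts divided by ``fps``.

    Returns ``(central_s, external_s, per_ring_s)`` with ``per_ring_s`` a
    vector of length ``geometry.n_rings``.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 2:
        p = p[:, None, :]
    r = np.linalg.norm(p, axis=-1)
    if np.any(r > geometry.radius + 1e-9):
        raise ValueError("position outside the arena")
    ring = np.minimum(
        np.floor(r / geometry.ring_width).astype(int), geometry.n_rings - 1
    )
    n_ind = p.shape[1]
    per_ring = np.array(
        [(ring == k).sum() / n_ind / fps for k in range(geometry.n_rings)]
    )
    n_central_rings = int(round(geometry.central_radius / geometry.ring_width))
    central = float(per_ring[:n_central_rings].sum())
    external = float(per_ring[n_central_rings:].sum())
    return central, external, per_ring


def fulton_k(weight_g: float, length_mm: float) -> float:
    """Fulton's condition factor K = weight * length^-3 * 10^4 (g mm^-3)."""
    if length_mm <= 0:
        raise ValueError("length must be > 0")
    if weight_g < 0:
        raise ValueError("weight must be >= 0")
    return weight_g / length_mm**3 * 1e4


def summarize_species(
    positions,
    species: Species | str,
    trial_id: str = "",
    geometry: ArenaGeometry = ArenaGeometry(),
    fps: float = 20.0,
) -> BehaviorSummary:
    """Full per-trial metric vector for one species' position array
    (n_frames, n_individuals, 2)."""
    p = _positions_3d(positions)
    central, external, per_ring = region_occupancy(p, geometry, fps)
    return BehaviorSummary(
        trial_id=trial_id,
        species=species.value if isinstance(species, Species) else str(species),
        afnd=afnd(p),
        aiid=aiid(p),
        distance_swam=distance_swam(p),
        turning_rate=turning_rate(p, 1.0 / fps),
        central_time=central,
        external_time=external,
        per_ring_time=tuple(per_ring),
    )
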