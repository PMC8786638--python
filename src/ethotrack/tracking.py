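"""Multi-species blob tracking.

Reconstructs per-individual tracks from grayscale frame stacks: multiple
thresholding and connected-component (blob) analysis, body-characteristic
species classification by blob area and mean gray level, optimal
track-to-detection assignment (Hungarian algorithm) run per species, and a
constant-velocity Kalman predictor that carries each track through missed
detections.

Pixel coordinates are image-native (origin top-left, y down); conversion to
arena-centred cm (y up) happens once, at the TrackSet boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.measure import label, regionprops

from .arena import ArenaGeometry, RenderConfig, Species, px_to_cm

__all__ = [
    "Detection",
    "Track",
    "TrackSet",
    "SpeciesCriteria",
    "default_criteria",
    "fit_thresholds",
    "detect",
    "classify_species",
    "assign",
    "KalmanState",
    "kalman_step",
    "track_trial",
]

#: Default assignment gate: maximum track-to-detection distance, in cm.
#: Generous bound above any plausible per-frame displacement at 20 fps.
DEFAULT_GATE_CM = 5.0


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class Detection:
    """One blob found in one frame (pixel units)."""

    frame: int
    centroid: np.ndarray        # (2,) px, (x, y)
    area: float                 # px^2
    mean_intensity: float       # gray level
    species: Optional[Species] = None   # set by classify_species; None = unknown

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.area <= 0:
            raise ValueError("detection area must be > 0")


@dataclass
class KalmanState:
    """Constant-velocity Kalman filter state: [x, y, vx, vy] and covariance."""

    x: np.ndarray               # (4,)
    P: np.ndarray               # (4, 4)


@dataclass
class Track:
    """One individual's trajectory, in cm, with per-sample provenance."""

    agent_id: str
    species: Species
    times: list = field(default_factory=list)            # s
    positions: list = field(default_factory=list)        # (2,) cm each
    sources: list = field(default_factory=list)          # "observed" | "predicted"
    filter_state: Optional[KalmanState] = None

    def as_arrays(self):
        return (
            np.asarray(self.times, dtype=float),
            np.asarray(self.positions, dtype=float),
            np.asarray(self.sources, dtype=object),
        )


@dataclass
class TrackSet:
    """All tracks of one trial on a common time base."""

    tracks: list
    fps: float
    geometry: ArenaGeometry
    cm_per_pixel: float

    def by_species(self, species: Species) -> list:
        return [t for t in self.tracks if t.species == species]

    def positions_of(self, species: Species) -> np.ndarray:
        """Stacked positions, shape (n_frames, n_individuals, 2) cm."""
        tracks = self.by_species(species)
        if not tracks:
            raise ValueError(f"no tracks of species {species}")
        return np.stack([np.asarray(t.positions, dtype=float) for t in tracks], axis=1)


@dataclass(frozen=True)
class SpeciesCriteria:
    """Per-species acceptance intervals on blob features.

    ``area`` and ``intensity`` map species to closed ``(lo, hi)`` intervals.
    Intervals must be pairwise disjoint on at least one feature so every
    blob matches at most one species.
    """

    area: dict
    intensity: dict

    def __post_init__(self) -> None:
        specs = list(self.area)
        for i, a in enumerate(specs):
            for b in specs[i + 1:]:
                area_overlap = _overlaps(self.area[a], self.area[b])
                int_overlap = _overlaps(self.intensity[a], self.intensity[b])
                if area_overlap and int_overlap:
                    raise ValueError(
                        f"criteria for {a} and {b} overlap on every feature"
                    )

    def match(self, area: float, intensity: float) -> Optional[Species]:
        hits = [
            sp for sp in self.area
            if _contains(self.area[sp], area) and _contains(self.intensity[sp], intensity)
        ]
        return hits[0] if len(hits) == 1 else None


def _overlaps(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _contains(iv, x: float) -> bool:
    return iv[0] <= x <= iv[1]


def default_criteria(rc: RenderConfig = RenderConfig(), slack: float = 0.45) -> SpeciesCriteria:
    """Criteria bracketing each species' nominal blob area and intensity."""
    area = {
        sp: ((1 - slack) * a, (1 + slack) * a)
        for sp, a in rc.species_blob_area.items()
    }
    intensity = {
        sp: (v - 30.0, v + 30.0) for sp, v in rc.species_intensity.items()
    }
    return SpeciesCriteria(area=area, intensity=intensity)


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------


def fit_thresholds(frames: Sequence[np.ndarray], n_levels: int = 3) -> list:
    """Fit gray-level thresholds from the first few frames.

    Pools the histogram of (up to) the first three frames and places
    thresholds at the valleys between the background mode and the blob
    intensity modes (multi-Otsu), mirroring a once-per-trial initialization.
    """
    from skimage.filters import threshold_multiotsu

    stack = np.stack([np.asarray(f) for f in frames[:3]]).astype(float)
    # Background dominates the histogram (blobs cover a tiny pixel
    # fraction), so Otsu on the full image misplaces the first valley.
    # Estimate the background level and spread robustly instead, and set the
    # lowest threshold a few noise deviations above it; the remaining levels
    # separate the blob intensity modes among foreground pixels only.
    bg = float(np.median(stack))
    sigma = 1.4826 * float(np.median(np.abs(stack - bg))) + 1e-6
    t0 = bg + 6.0 * sigma
    fg = stack[stack > t0]
    if n_levels <= 1 or np.unique(fg).size < n_levels + 1:
        return [t0]
    inner = threshold_multiotsu(fg, classes=n_levels)
    return [t0] + [float(t) for t in inner]


def detect(
    frame: np.ndarray,
    thresholds: Sequence[float],
    area_bounds: dict | tuple,
    frame_index: int = 0,
    merge_radius_px: float = 3.0,
    intensity_bounds: Optional[dict] = None,
) -> list:
    """Find candidate animal/robot blobs in one grayscale frame.

    Connected components are extracted above each threshold level, from the
    highest level down, and merged by centroid proximity: a bright blob is
    kept once, from the highest level that isolates it, so animals standing
    out above a dimmer neighbour (e.g. the robot) separate cleanly even when
    their silhouettes touch at lower levels.  Components whose area falls
    outside every supplied bound are discarded as noise.

    Parameters
    ----------
    frame : 2-D uint8/float array
    thresholds : increasing gray levels; at least one
    area_bounds : mapping species -> (lo, hi) px^2, or a single (lo, hi)
    intensity_bounds : optional mapping with the same keys as area_bounds;
        when given, a component only counts as one body (or a mergeable
        pair) of a species if its mean gray level also fits that species,
        which disambiguates e.g. a touching pair of one species from a
        single body of a larger one

    Returns
    -------
    list of Detection
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("detect expects a single-channel image")
    if frame.size == 0:
        raise ValueError("empty image")
    if not thresholds:
        raise ValueError("at least one threshold required")
    lo_gray, hi_gray = float(frame.min()), 255.0
    for t in thresholds:
        if not 0 <= t <= 255:
            raise ValueError(f"threshold {t} outside gray range [0, 255]")

    if isinstance(area_bounds, dict):
        keys = list(area_bounds)
        bounds = [area_bounds[k] for k in keys]
        ibounds = [
            intensity_bounds.get(k, (0.0, 255.0)) if intensity_bounds else (0.0, 255.0)
            for k in keys
        ]
    else:
        bounds = [tuple(area_bounds)]
        ibounds = [(0.0, 255.0)]

    def _add(c: np.ndarray, area: float, intensity: float) -> None:
        if any(np.linalg.norm(c - d.centroid) < merge_radius_px for d in detections):
            return
        detections.append(
            Detection(frame=frame_index, centroid=c, area=area,
                      mean_intensity=intensity)
        )

    detections: list[Detection] = []
    for thr in sorted(thresholds, reverse=True):
        labeled = label(frame > thr)
        for rp in regionprops(labeled, intensity_image=frame):
            cy, cx = rp.centroid
            inten = float(rp.intensity_mean)
            if any(
                lo <= rp.area <= hi and ilo <= inten <= ihi
                for (lo, hi), (ilo, ihi) in zip(bounds, ibounds)
            ):
                _add(np.array([cx, cy]), float(rp.area), inten)
            elif any(
                2 * lo <= rp.area <= 2 * hi and ilo <= inten <= ihi
                for (lo, hi), (ilo, ihi) in zip(bounds, ibounds)
            ):
                # Two same-species animals touching: split the double-size
                # component into two blobs along its major axis.
                o = rp.orientation
                # Major-axis direction in (col, row) pixel coordinates.
                off = rp.axis_major_length / 4.0 * np.array([-math.sin(o), -math.cos(o)])
                for sgn in (+1.0, -1.0):
                    _add(np.array([cx, cy]) + sgn * off,
                         float(rp.area) / 2.0, float(rp.intensity_mean))
    return detections


def classify_species(
    detections: Sequence[Detection],
    criteria: SpeciesCriteria,
    motion_context: Optional[dict] = None,
) -> list:
    """Label each detection with the unique species whose area and intensity
    intervals contain it; ambiguous or unmatched blobs become unknown
    (``species=None``).

    ``motion_context`` (species -> typical speed, px/frame) is consulted only
    to break ties when a blob satisfies more than one species' intervals.
    """
    out = []
    for d in detections:
        hits = [
            sp for sp in criteria.area
            if _contains(criteria.area[sp], d.area)
            and _contains(criteria.intensity[sp], d.mean_intensity)
        ]
        if len(hits) == 1:
            d.species = hits[0]
        elif len(hits) > 1 and motion_context:
            # Tie-break by closeness of blob area to the species' nominal
            # centre, weighted by available motion context.
            d.species = min(
                hits,
                key=lambda sp: abs(d.area - np.mean(criteria.area[sp]))
                + abs(motion_context.get(sp, 0.0)),
            )
        else:
            d.species = None
        out.append(d)
    return out


# --------------------------------------------------------------------------
# Assignment
# --------------------------------------------------------------------------


def assign(
    predicted_positions: np.ndarray,
    detections: np.ndarray,
    gate: float = np.inf,
) -> tuple[list, list, list]:
    """Optimally match predicted track positions to detections.

    Solves the rectangular assignment problem minimising total Euclidean
    distance (Hungarian/Munkres algorithm); matched pairs farther apart than
    ``gate`` are subsequently unmatched.

    Returns ``(matches, unmatched_tracks, unmatched_detections)`` where
    ``matches`` is a list of ``(track_index, detection_index)``.
    """
    predicted_positions = np.asarray(predicted_positions, dtype=float).reshape(-1, 2)
    detections = np.asarray(detections, dtype=float).reshape(-1, 2)
    n_t, n_d = len(predicted_positions), len(detections)
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))
    cost = np.linalg.norm(
        predicted_positions[:, None, :] - detections[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= gate]
    matched_t = {r for r, _ in matches}
    matched_d = {c for _, c in matches}
    return (
        matches,
        [i for i in range(n_t) if i not in matched_t],
        [j for j in range(n_d) if j not in matched_d],
    )


# --------------------------------------------------------------------------
# Kalman prediction
# --------------------------------------------------------------------------

def _cv_matrices(dt: float, process_noise: float):
    F = np.array(
        [[1, 0, dt, 0],
         [0, 1, 0, dt],
         [0, 0, 1, 0],
         [0, 0, 0, 1]], dtype=float
    )
    # White-acceleration process noise for a constant-velocity model.
    q = process_noise
    G = np.array([[dt**2 / 2, 0], [0, dt**2 / 2], [dt, 0], [0, dt]])
    Q = q * G @ G.T
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    return F, Q, H


def kalman_step(
    track: Track,
    observation: Optional[np.ndarray],
    dt: float,
    process_noise: float = 200.0,
    measurement_noise: float = 0.001,
) -> Track:
    """Advance a track's constant-velocity Kalman filter by one frame.

    With an observation, runs the standard predict-update cycle and appends
    an ``observed`` sample; without one, appends the predicted position
    flagged ``predicted``.  ``process_noise`` is the white-acceleration
    spectral density (cm^2/s^3), ``measurement_noise`` the positional
    variance of observations (cm^2).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if observation is not None:
        observation = np.asarray(observation, dtype=float)
        if not np.all(np.isfinite(observation)):
            raise ValueError("observation must be finite")

    t_next = (track.times[-1] + dt) if track.times else 0.0

    if track.filter_state is None:
        if observation is None:
            raise ValueError("cannot start a track without an observation")
        x = np.array([observation[0], observation[1], 0.0, 0.0])
        P = np.diag([measurement_noise, measurement_noise, 25.0, 25.0])
        track.filter_state = KalmanState(x=x, P=P)
        track.times.append(t_next)
        track.positions.append(observation.copy())
        track.sources.append("observed")
        return track

    F, Q, H = _cv_matrices(dt, process_noise)
    st = track.filter_state
    x_pred = F @ st.x
    P_pred = F @ st.P @ F.T + Q

    if observation is None:
        st.x, st.P = x_pred, P_pred
        track.times.append(t_next)
        track.positions.append(x_pred[:2].copy())
        track.sources.append("predicted")
        return track

    R = measurement_noise * np.eye(2)
    y = observation - H @ x_pred
    S = H @ P_pred @ H.T + R
    K = P_pred @ H.T @ np.linalg.inv(S)
    st.x = x_pred + K @ y
    st.P = (np.eye(4) - K @ H) @ P_pred
    track.times.append(t_next)
    track.positions.append(st.x[:2].copy())
    track.sources.append("observed")
    return track


def _soft_update(track: Track, centroid: np.ndarray, r_soft: float) -> None:
    """Measurement update with inflated variance, used for merged blobs.

    Adjusts the filter state and the last appended position toward
    ``centroid`` without changing the sample's predicted flag."""
    st = track.filter_state
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    R = r_soft * np.eye(2)
    y = np.asarray(centroid, dtype=float) - H @ st.x
    S = H @ st.P @ H.T + R
    K = st.P @ H.T @ np.linalg.inv(S)
    st.x = st.x + K @ y
    st.P = (np.eye(4) - K @ H) @ st.P
    track.positions[-1] = st.x[:2].copy()


# --------------------------------------------------------------------------
# Per-trial tracking
# --------------------------------------------------------------------------


def track_trial(
    frames: Sequence[np.ndarray],
    rc: RenderConfig = RenderConfig(),
    geometry: ArenaGeometry = ArenaGeometry(),
    fps: float = 20.0,
    criteria: Optional[SpeciesCriteria] = None,
    thresholds: Optional[Sequence[float]] = None,
    group_sizes: Optional[dict] = None,
    gate_cm: float = DEFAULT_GATE_CM,
    process_noise: float = 200.0,
    measurement_noise: float = 0.001,
) -> TrackSet:
    """Track all individuals through a grayscale frame stack.

    Per frame: detect blobs above the fitted thresholds, classify them by
    body characteristics, assign them per species to existing tracks
    (Hungarian with a distance gate), update each track's Kalman filter, and
    fill misses with constant-velocity predictions.  Tracks are seeded on
    the first frame with the configured group sizes (closed population, no
    mid-trial birth or death); the robot's blobs fall in their own intensity
    band and form a separate track excluded from animal analyses.

    Returns a TrackSet in arena-centred cm.
    """
    frames = list(frames)
    if not frames:
        return TrackSet(tracks=[], fps=fps, geometry=geometry,
                        cm_per_pixel=rc.cm_per_pixel)
    shape = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape:
            raise ValueError(f"frame {i} changed size mid-stack")

    if criteria is None:
        criteria = default_criteria(rc)
    if thresholds is None:
        thresholds = fit_thresholds(frames, n_levels=3)
    if group_sizes is None:
        group_sizes = {Species.MOSQUITOFISH: 6, Species.TADPOLE: 6, Species.ROBOT: 1}

    area_bounds = {sp: criteria.area[sp] for sp in criteria.area}
    dt = 1.0 / fps
    gate_px = gate_cm / rc.cm_per_pixel
    # Filter parameters are supplied in cm; convert to pixel units.
    q_px = process_noise / rc.cm_per_pixel**2
    r_px = measurement_noise / rc.cm_per_pixel**2

    tracks_px: dict[Species, list[Track]] = {}
    counters = {sp: 0 for sp in group_sizes}

    for f_idx, frame in enumerate(frames):
        dets = classify_species(
            detect(frame, thresholds, area_bounds, frame_index=f_idx,
                   intensity_bounds=criteria.intensity),
            criteria,
        )
        for sp, n_max in group_sizes.items():
            sp_dets = [d for d in dets if d.species == sp]
            if sp not in tracks_px:
                tracks_px[sp] = []
            existing = tracks_px[sp]

            # Seed tracks from the first frames up to the known group size.
            while len(existing) < n_max and len(sp_dets) > len(existing):
                tid = f"{sp.value}_{counters[sp]}"
                counters[sp] += 1
                existing.append(Track(agent_id=tid, species=sp))

            started = [t for t in existing if t.filter_state is not None]
            fresh = [t for t in existing if t.filter_state is None]

            preds = np.array(
                [t.filter_state.x[:2] + t.filter_state.x[2:] * dt for t in started]
            ).reshape(-1, 2)
            det_pos = np.array([d.centroid for d in sp_dets]).reshape(-1, 2)
            matches, unmatched_t, unmatched_d = assign(preds, det_pos, gate_px)

            for ti, di in matches:
                kalman_step(started[ti], sp_dets[di].centroid, dt, q_px, r_px)
            for ti in unmatched_t:
                tr = started[ti]
                kalman_step(tr, None, dt, q_px, r_px)
                # Merged-measurement update: when two animals fuse into one
                # blob, the unassigned track coasts, but if its prediction
                # lies within a same-species blob's footprint that blob's
                # centroid still constrains the position.  Apply it as a
                # high-variance update; the sample stays flagged predicted
                # because no detection was assigned to this track.
                if sp_dets:
                    d_near = min(
                        sp_dets,
                        key=lambda d: np.linalg.norm(d.centroid - tr.positions[-1]),
                    )
                    radius = math.sqrt(d_near.area / math.pi)
                    if np.linalg.norm(d_near.centroid - tr.positions[-1]) < 1.5 * radius:
                        _soft_update(tr, d_near.centroid, r_soft=radius**2)
            # Leftover detections start fresh tracks (first frames only).
            for t, di in zip(fresh, unmatched_d):
                kalman_step(t, sp_dets[di].centroid, dt, q_px, r_px)
                if f_idx > 0:
                    # Keep a common time base: backfill a late-started track
                    # with its first observation, flagged predicted.
                    first = t.positions[0]
                    t.times = [k * dt for k in range(f_idx + 1)]
                    t.positions = [first.copy() for _ in range(f_idx)] + t.positions
                    t.sources = ["predicted"] * f_idx + t.sources

    # Convert pixel tracks to arena-centred cm.
    out = []
    for sp, ts in tracks_px.items():
        for t in ts:
            if not t.times:
                continue
            pos_cm = px_to_cm(np.asarray(t.positions, dtype=float), rc)
            out.append(
                Track(
                    agent_id=t.agent_id,
                    species=sp,
                    times=list(np.asarray(t.times)),
                    positions=[p for p in pos_cm],
                    sources=list(t.sources),
                    filter_state=t.filter_state,
                )
            )
    return TrackSet(tracks=out, fps=fps, geometry=geometry, cm_per_pixel=rc.cm_per_pixel)
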