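"""Synthetic arena: agent-based trials with an interactive robotic predator.

Generates ground-truth trials (trajectories plus attack logs) and synthetic
video frames emulating a circular 42-cm assay arena holding six mosquitofish,
six tadpoles and, in the exposed treatment, one robotic predator.  The robot
patrols a stored closed curve and launches attacks on the mosquitofish
closest to the tadpoles at roughly one per minute, with three-tier kinematics
(contact / inspection / pursuit) bounded by a 20 cm/s speed cap and a
20 cm/s^2 acceleration cap.

All lengths are in cm, times in seconds, angles in radians, positions in
arena-centred coordinates (y up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Species",
    "Tier",
    "ArenaGeometry",
    "AgentState",
    "AttackEvent",
    "CouplingSpec",
    "RenderConfig",
    "RenderResult",
    "TrialRecording",
    "ControllerPhase",
    "MAX_ATTACK_DURATION_S",
    "ROBOT_MAX_SPEED",
    "ROBOT_MAX_ACCEL",
    "CONTACT_RADIUS",
    "INSPECTION_RADIUS",
    "STANDOFF",
    "classify_tier",
    "schedule_attacks",
    "attack_controller_step",
    "simulate_trial",
    "render_frames",
    "patrol_curve",
]

# --------------------------------------------------------------------------
# Constants of the robotic platform
# --------------------------------------------------------------------------

ROBOT_MAX_SPEED = 20.0      # cm/s
ROBOT_MAX_ACCEL = 20.0      # cm/s^2
CONTACT_RADIUS = 1.0        # cm; closer than this -> contact tier
INSPECTION_RADIUS = 10.0    # cm; up to this -> inspection tier
STANDOFF = 1.0              # cm; approach stops about here
HOLD_TIME = 1.0             # s; pause after reaching the target
PATROL_SPEED = 6.0          # cm/s along the stored patrol curve

#: Upper bound on the duration of a single attack (pursuit out to the far
#: wall, hold, and return), used by the scheduler to guarantee that attacks
#: never overlap: out/back legs of at most ~3 s each plus the 1-s hold,
#: with margin for a moving target.
MAX_ATTACK_DURATION_S = 7.5


class Species(str, Enum):
    MOSQUITOFISH = "mosquitofish"
    TADPOLE = "tadpole"
    ROBOT = "robot"


class Tier(str, Enum):
    CONTACT = "contact"        # target closer than 1 cm
    INSPECTION = "inspection"  # target between 1 and 10 cm
    PURSUIT = "pursuit"        # target farther than 10 cm


def classify_tier(distance: float) -> Tier:
    """Attack tier for a robot-target distance at trigger time."""
    if distance < CONTACT_RADIUS:
        return Tier.CONTACT
    if distance <= INSPECTION_RADIUS:
        return Tier.INSPECTION
    return Tier.PURSUIT


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular assay arena partitioned into concentric rings.

    The default matches a 42-cm-diameter tank whose 21-cm radius is split
    into seven 3-cm rings; rings 0-4 (0-15 cm) form the central region and
    rings 5-6 (15-21 cm) the external region.
    """

    diameter: float = 42.0
    ring_width: float = 3.0
    n_rings: int = 7
    central_radius: float = 15.0
    water_depth: float = 10.0  # metadata only

    def __post_init__(self) -> None:
        if not math.isclose(self.n_rings * self.ring_width, self.radius):
            raise ValueError(
                f"n_rings * ring_width must equal the arena radius "
                f"({self.n_rings} * {self.ring_width} != {self.radius})"
            )
        if not 0 < self.central_radius < self.radius:
            raise ValueError("central_radius must lie inside the arena")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class AgentState:
    """Planar kinematic state of one agent (animal or robot)."""

    agent_id: str
    species: Species
    position: np.ndarray   # (2,) cm, arena-centred
    velocity: np.ndarray   # (2,) cm/s
    heading: float         # rad in [-pi, pi)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.heading = float(wrap_angle(self.heading))


@dataclass(frozen=True)
class AttackEvent:
    t_trigger: float
    target_id: str
    initial_distance: float
    tier: Tier
    t_complete: float

    def __post_init__(self) -> None:
        if self.t_complete <= self.t_trigger:
            raise ValueError("t_complete must exceed t_trigger")
        if self.tier != classify_tier(self.initial_distance):
            raise ValueError(
                f"tier {self.tier} inconsistent with initial distance "
                f"{self.initial_distance:.2f} cm"
            )


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth directed behavioural coupling between the groups.

    ``fish_fear_gain`` scales mosquitofish repulsion from the robot and the
    accompanying increase in shoal cohesion.  ``tadpole_from_fish_gain``
    modulates tadpole turning noise by the fish group's recent turning
    activity (half a second earlier), and ``fish_from_tadpole_gain`` the
    reverse; ``(a, 0)`` with ``a > 0`` therefore defines a unidirectional
    fish-to-tadpole interaction that the information-flow stage should
    recover, and all-zero gains define independence.
    """

    fish_fear_gain: float = 1.0
    tadpole_from_fish_gain: float = 1.0
    fish_from_tadpole_gain: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fish_fear_gain", "tadpole_from_fish_gain", "fish_from_tadpole_gain"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class RenderConfig:
    """How trials are rasterised into grayscale frames.

    Species are separable by blob area and mean gray level, mimicking the
    coloration/size cues a body-characteristic filter exploits; the robot
    occupies its own intensity band so the tracker can suppress it.
    """

    image_size: tuple[int, int] = (480, 480)        # (height, width) px
    cm_per_pixel: float = 0.1
    species_blob_area: dict = field(
        default_factory=lambda: {
            Species.MOSQUITOFISH: 80.0,   # px^2
            Species.TADPOLE: 40.0,
            Species.ROBOT: 220.0,
        }
    )
    species_intensity: dict = field(
        default_factory=lambda: {
            Species.MOSQUITOFISH: 130.0,  # mean gray level
            Species.TADPOLE: 210.0,
            Species.ROBOT: 70.0,
        }
    )
    background: float = 10.0
    noise_sd: float = 3.0
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        areas = sorted(self.species_blob_area.values())
        if any(math.isclose(a, b) for a, b in zip(areas, areas[1:])):
            raise ValueError("species blob areas must be pairwise distinct")
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must be in [0, 1)")


@dataclass
class TrialRecording:
    """One simulated trial: dense trajectories plus the attack log.

    Positions and headings are stored as arrays of shape ``(n_frames,
    n_agents, 2)`` and ``(n_frames, n_agents)``; ``frame_states`` exposes the
    per-frame list-of-AgentState view.
    """

    fps: float
    duration: float
    agent_ids: list[str]
    species: list[Species]
    positions: np.ndarray
    headings: np.ndarray
    attacks: list[AttackEvent]
    treatment: str                 # "non_exposed" | "robot_exposed"
    seed: int
    coupling: CouplingSpec
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def species_index(self, species: Species) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == species], dtype=int)

    def frame_states(self, frame: int) -> list[AgentState]:
        dt = 1.0 / self.fps
        if frame + 1 < self.n_frames:
            vel = (self.positions[frame + 1] - self.positions[frame]) / dt
        elif self.n_frames > 1:
            vel = (self.positions[frame] - self.positions[frame - 1]) / dt
        else:
            vel = np.zeros_like(self.positions[frame])
        return [
            AgentState(self.agent_ids[i], self.species[i],
                       self.positions[frame, i], vel[i], self.headings[frame, i])
            for i in range(self.n_agents)
        ]


@dataclass
class RenderResult:
    """Grayscale frame stack plus the ground-truth blob correspondence."""

    frames: np.ndarray          # (n_frames, H, W) uint8
    truth: "object"             # pandas.DataFrame: frame, agent_id, species, x_px, y_px, visible
    config: RenderConfig


# --------------------------------------------------------------------------
# Small helpers
# --------------------------------------------------------------------------


def wrap_angle(theta):
    """Wrap angle(s) to [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % (2 * np.pi) - np.pi


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros_like(v)


# --------------------------------------------------------------------------
# Attack scheduling
# --------------------------------------------------------------------------


def schedule_attacks(
    duration: float,
    rate: float = 1.0,
    standardize_to: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw attack trigger times for one trial.

    Triggers are jittered uniformly within consecutive bins whose spacing
    reserves ``MAX_ATTACK_DURATION_S`` of busy time per attack, so successive
    triggers are always separated by at least the longest possible attack and
    every attack completes before the trial ends.  Because of the reserved
    busy time an unstandardized hour at one attack per minute yields fewer
    than 60 triggers, as in the live experiment.

    Parameters
    ----------
    duration : float
        Trial length in seconds.
    rate : float
        Nominal attack frequency in attacks per minute.
    standardize_to : int, optional
        If given, return exactly this many triggers (spread over the trial);
        must be feasible for the duration.
    seed : int
        Seed for the jitter.

    Returns
    -------
    numpy.ndarray
        Strictly increasing trigger times in ``[0, duration)``.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    interval = 60.0 / rate

    if standardize_to is not None:
        n = int(standardize_to)
        if n < 0:
            raise ValueError("standardize_to must be >= 0")
        if n == 0:
            return np.empty(0)
        if n > math.floor(duration / 60.0 * rate):
            raise ValueError(
                f"standardize_to={n} infeasible for duration {duration} s at "
                f"{rate}/min (max {math.floor(duration / 60.0 * rate)})"
            )
        cycle = duration / n
        jitter = cycle - MAX_ATTACK_DURATION_S
        if jitter <= 0:
            raise ValueError(
                f"standardize_to={n} leaves no room for {MAX_ATTACK_DURATION_S}-s attacks"
            )
        return np.arange(n) * cycle + rng.uniform(0.0, jitter, size=n)

    cycle = interval + MAX_ATTACK_DURATION_S
    n_bins = int(math.ceil(duration / cycle)) if duration > 0 else 0
    starts = np.arange(n_bins) * cycle
    triggers = starts + rng.uniform(0.0, interval, size=n_bins)
    return triggers[triggers + MAX_ATTACK_DURATION_S <= duration]


# --------------------------------------------------------------------------
# Robot attack controller
# --------------------------------------------------------------------------


@dataclass
class ControllerPhase:
    """State of the robot controller's attack state machine.

    ``name`` is one of ``idle-patrol``, ``orient``, ``pursue``, ``hold``,
    ``return``.  ``home_position``/``home_heading`` store the pre-attack pose
    the robot restores after an attack; ``tier`` is fixed at trigger time.
    """

    name: str = "idle-patrol"
    tier: Optional[Tier] = None
    hold_remaining: float = 0.0
    home_position: Optional[np.ndarray] = None
    home_heading: float = 0.0


def _approach_leg(position: np.ndarray, speed: float, goal: np.ndarray,
                  standoff: float, dt: float):
    """One step of a straight approach toward `goal`, ending `standoff` cm
    short of it.

    The speed ramps at exactly +-20 cm/s^2 (capped at 20 cm/s) and the
    position advances with the midpoint speed, under which a ramp-down from
    the braking envelope v = sqrt(2a*s) covers exactly s: the leg terminates
    at the stop point with zero speed, never exceeding either limit.
    Returns (new_position, new_speed, arrived).
    """
    a = ROBOT_MAX_ACCEL
    to_goal = goal - position
    distance = float(np.linalg.norm(to_goal))
    remaining = max(0.0, distance - standoff)
    # Largest admissible next speed: after advancing (v+v')/2*dt, braking
    # from v' at a must still fit in what is left of the leg.
    arg = (a * dt / 2.0) ** 2 + 2.0 * a * max(0.0, remaining - speed * dt / 2.0)
    v_req = max(0.0, -a * dt / 2.0 + math.sqrt(arg))
    v_new = max(0.0, min(min(ROBOT_MAX_SPEED, v_req), speed + a * dt))
    v_new = max(v_new, max(0.0, speed - a * dt))
    step_len = (speed + v_new) / 2.0 * dt
    direction = _unit(to_goal)
    if step_len >= remaining - 1e-9 and v_new <= a * dt + 1e-9:
        return position + direction * remaining, 0.0, True
    return position + direction * min(step_len, remaining), v_new, False


def attack_controller_step(
    robot: AgentState,
    target_position: np.ndarray,
    phase: ControllerPhase,
    dt: float,
    geometry: ArenaGeometry = ArenaGeometry(),
) -> tuple[AgentState, ControllerPhase]:
    """Advance the robot's attack state machine by one time step.

    Implements the three-tier rule: within 1 cm the robot only turns toward
    the fish and holds for 1 s; farther away it accelerates at 20 cm/s^2
    (capped at 20 cm/s) toward the fish, stops at about 1 cm, holds 1 s, and
    returns to its pre-attack position and heading.  The commanded speed
    never exceeds 20 cm/s and the speed ramp never exceeds 20 cm/s^2.

    Returns the commanded robot state and the next phase.  In ``idle-patrol``
    the state is returned unchanged (patrol progression is the simulator's
    job, not the attack controller's).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target_position = np.asarray(target_position, dtype=float)
    if np.linalg.norm(target_position) > geometry.radius + 1e-9:
        raise ValueError("target position lies outside the arena")

    robot = replace(robot)
    to_target = target_position - robot.position
    distance = float(np.linalg.norm(to_target))
    speed = float(np.linalg.norm(robot.velocity))

    if phase.name == "idle-patrol":
        return robot, phase

    if phase.name == "orient":
        # Ramp any residual patrol speed down at <=20 cm/s^2 before engaging,
        # so the speed profile stays within the drive's ramp limit.
        if speed > 1e-9:
            v_new = max(0.0, speed - ROBOT_MAX_ACCEL * dt)
            direction = _unit(robot.velocity)
            robot.position = robot.position + direction * v_new * dt
            robot.velocity = direction * v_new
            return robot, phase
        # Stopped: classify the tier and remember the pre-attack pose.
        tier = classify_tier(distance) if phase.tier is None else phase.tier
        nxt = ControllerPhase(
            name="hold" if tier == Tier.CONTACT else "pursue",
            tier=tier,
            hold_remaining=HOLD_TIME if tier == Tier.CONTACT else 0.0,
            home_position=robot.position.copy(),
            home_heading=robot.heading,
        )
        if tier == Tier.CONTACT:
            # Turn toward the fish without translating; degenerate
            # zero-distance targets leave the heading unchanged.
            if distance > 0:
                robot.heading = float(math.atan2(to_target[1], to_target[0]))
            robot.velocity = np.zeros(2)
        return robot, nxt

    if phase.name == "pursue":
        new_pos, v_new, arrived = _approach_leg(
            robot.position, speed, target_position, STANDOFF, dt
        )
        direction = _unit(to_target)
        robot.position = new_pos
        robot.velocity = direction * v_new
        if distance > 0:
            robot.heading = float(math.atan2(to_target[1], to_target[0]))
        if arrived:
            robot.velocity = np.zeros(2)
            return robot, replace(phase, name="hold", hold_remaining=HOLD_TIME)
        return robot, phase

    if phase.name == "hold":
        robot.velocity = np.zeros(2)
        hold = phase.hold_remaining - dt
        if hold > 1e-9:
            return robot, replace(phase, hold_remaining=hold)
        if phase.tier == Tier.CONTACT:
            # Contact attacks end in place: restore the initial heading.
            robot.heading = phase.home_heading
            return robot, ControllerPhase(name="idle-patrol")
        return robot, replace(phase, name="return", hold_remaining=0.0)

    if phase.name == "return":
        new_pos, v_new, arrived = _approach_leg(
            robot.position, speed, phase.home_position, 0.0, dt
        )
        direction = _unit(phase.home_position - robot.position)
        robot.position = new_pos
        robot.velocity = direction * v_new
        if arrived:
            robot.position = phase.home_position.copy()
            robot.velocity = np.zeros(2)
            robot.heading = phase.home_heading
            return robot, ControllerPhase(name="idle-patrol")
        return robot, phase

    raise ValueError(f"unknown controller phase {phase.name!r}")


# --------------------------------------------------------------------------
# Patrol trajectory
# --------------------------------------------------------------------------


def patrol_curve(n_points: int = 2000, radius: float = 10.5) -> np.ndarray:
    """Stored closed patrol curve: a smoothed Lissajous figure inside the
    central region, resampled to constant arc-length spacing.

    Returns an ``(n_points, 2)`` array of cm positions; consecutive points
    are equidistant so traversal at constant index rate gives constant speed.
    """
    u = np.linspace(0.0, 2 * np.pi, 8192, endpoint=False)
    # Phase pi/2 keeps the two coordinates from reaching their extremes
    # simultaneously, so the figure has no cusp and can be traversed at
    # constant speed.
    raw = np.stack([radius * np.sin(2 * u), radius * np.sin(3 * u + np.pi / 2)], axis=1)
    closed = np.vstack([raw, raw[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_points, endpoint=False)
    return np.stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])],
        axis=1,
    )


# --------------------------------------------------------------------------
# Trial simulation
# --------------------------------------------------------------------------

# Behavioural parameters of the agent model (cm, s, rad).
_FISH_SPEED_MEAN = 6.0
_FISH_SPEED_SD = 2.0
_FISH_SPEED_RELAX = 1.0          # 1/s, OU relaxation of speed
_FISH_TURN_SD = 1.6              # rad/sqrt(s), heading diffusion
_FISH_MAX_TURN = 8.0             # rad/s steering limit
_FISH_W_COHESION = 0.5
_FISH_W_ALIGNMENT = 0.8
_FISH_W_PERSIST = 1.2
_FISH_SEP_RADIUS = 2.5           # cm, zone of repulsion between shoal-mates
_FISH_W_SEP = 2.0
_FISH_FEAR_RADIUS = 10.0         # cm, robot perception radius
_FISH_FEAR_WEIGHT = 3.0

_TAD_SPEED_MEAN = 2.5
_TAD_SPEED_SD = 1.0
_TAD_TURN_SD = 1.2
_TAD_MAX_TURN = 6.0

_WALL_MARGIN = 0.5               # cm kept clear of the physical wall

_COUPLING_WINDOW_S = 0.5         # s; activity window driving cross-species modulation


def _reflect(pos: np.ndarray, heading: np.ndarray, r_max: float):
    """Reflective wall: mirror positions across the circle and flip the
    radial heading component for agents that stepped outside."""
    r = np.linalg.norm(pos, axis=1)
    out = r > r_max
    if np.any(out):
        n = pos[out] / r[out, None]
        pos[out] = n * (2 * r_max - r[out])[:, None]
        h = np.stack([np.cos(heading[out]), np.sin(heading[out])], axis=1)
        h -= 2 * np.sum(h * n, axis=1, keepdims=True) * n
        heading[out] = np.arctan2(h[:, 1], h[:, 0])
    return pos, heading


def simulate_trial(
    geometry: ArenaGeometry = ArenaGeometry(),
    coupling: CouplingSpec = CouplingSpec(),
    treatment: str = "non_exposed",
    duration: float = 3600.0,
    fps: float = 20.0,
    seed: int = 0,
    n_fish: int = 6,
    n_tadpoles: int = 6,
    attack_rate: float = 1.0,
    standardize_attacks: Optional[int] = None,
) -> TrialRecording:
    """Simulate one arena trial and return its ground-truth recording.

    Mosquitofish follow a correlated random walk with shoal cohesion and
    alignment; within a 10-cm perception radius of the robot they are
    repelled (and cohere more strongly), scaled by ``fish_fear_gain``.
    Tadpoles follow a slower correlated random walk whose turning noise is
    modulated by the fish group's turning activity in the previous
    half-second window, scaled by ``tadpole_from_fish_gain`` (and vice versa
    for ``fish_from_tadpole_gain``), giving the directed couplings the
    information-flow stage is meant to recover.  In the exposed treatment the
    robot patrols a stored closed curve and executes scheduled attacks on the
    mosquitofish nearest to any tadpole.

    Deterministic for fixed arguments: same seed, same recording.
    """
    if treatment not in ("non_exposed", "robot_exposed"):
        raise ValueError(f"unknown treatment {treatment!r}")
    if fps <= 0 or duration < 0:
        raise ValueError("fps must be > 0 and duration >= 0")
    n_frames = round(fps * duration)
    if abs(n_frames - fps * duration) > 1e-9:
        raise ValueError("duration must be an integer number of frames at this fps")
    dt = 1.0 / fps
    rng = np.random.default_rng(seed)
    r_max = geometry.radius - _WALL_MARGIN

    has_robot = treatment == "robot_exposed"
    n_animals = n_fish + n_tadpoles
    n_agents = n_animals + (1 if has_robot else 0)
    agent_ids = [f"fish_{i}" for i in range(n_fish)] + [
        f"tadpole_{i}" for i in range(n_tadpoles)
    ] + (["robot"] if has_robot else [])
    species = (
        [Species.MOSQUITOFISH] * n_fish
        + [Species.TADPOLE] * n_tadpoles
        + ([Species.ROBOT] if has_robot else [])
    )
    fish = slice(0, n_fish)
    tads = slice(n_fish, n_animals)

    # Initial animal states: scattered in the inner half of the arena.
    r0 = geometry.radius * 0.5 * np.sqrt(rng.uniform(size=n_animals))
    a0 = rng.uniform(-np.pi, np.pi, size=n_animals)
    pos = np.stack([r0 * np.cos(a0), r0 * np.sin(a0)], axis=1)
    heading = rng.uniform(-np.pi, np.pi, size=n_animals)
    speed = np.concatenate([
        np.clip(rng.normal(_FISH_SPEED_MEAN, _FISH_SPEED_SD, n_fish), 0.5, 15.0),
        np.clip(rng.normal(_TAD_SPEED_MEAN, _TAD_SPEED_SD, n_tadpoles), 0.2, 8.0),
    ])

    positions = np.empty((n_frames, n_agents, 2))
    headings = np.empty((n_frames, n_agents))

    # Robot bookkeeping.
    curve = patrol_curve()
    seg_len = float(np.linalg.norm(curve[1] - curve[0]))

    def curve_point(u: float) -> np.ndarray:
        i = int(u) % len(curve)
        frac = u - int(u)
        return curve[i] * (1.0 - frac) + curve[(i + 1) % len(curve)] * frac

    patrol_pos = 0.0
    patrol_speed = 0.0
    halting = False
    robot_state = AgentState("robot", Species.ROBOT, curve[0].copy(), np.zeros(2), 0.0)
    phase = ControllerPhase()
    attacks: list[AttackEvent] = []
    pending: Optional[dict] = None
    if has_robot:
        att_seed = (seed * 1000003 + 17) % (2**31)
        trigger_times = list(
            schedule_attacks(duration, attack_rate, standardize_attacks, att_seed)
        )
    else:
        trigger_times = []
    next_trigger = trigger_times.pop(0) if trigger_times else None

    # Cross-species activity modulation, updated once per half-second
    # window.  The responding species reacts with a latency of one full
    # window beyond the update boundary (0.5-1.0 s), a plausible behavioural
    # reaction time; the latency also keeps the induced information flow
    # strictly forward at the half-second symbol scale.
    win = max(1, round(_COUPLING_WINDOW_S * fps))
    fish_turn_accum = 0.0
    tad_turn_accum = 0.0
    # Baseline per-step mean |heading increment| of an undisturbed walker.
    fish_turn_base = _FISH_TURN_SD * math.sqrt(dt) * math.sqrt(2 / math.pi)
    tad_turn_base = _TAD_TURN_SD * math.sqrt(dt) * math.sqrt(2 / math.pi)
    fish_act = fish_act_old = 1.0   # window activity factors, ~1 at baseline
    tad_act = tad_act_old = 1.0

    for f in range(n_frames):
        t = f * dt
        positions[f, :n_animals] = pos
        headings[f, :n_animals] = heading
        if has_robot:
            positions[f, n_animals] = robot_state.position
            headings[f, n_animals] = robot_state.heading

        # ---- robot update -------------------------------------------------
        if has_robot:
            if (
                phase.name == "idle-patrol"
                and not halting
                and next_trigger is not None
                and t >= next_trigger
            ):
                # Target the mosquitofish closest to its nearest tadpole.
                d_ft = np.linalg.norm(
                    pos[fish][:, None, :] - pos[tads][None, :, :], axis=2
                )
                target_idx = int(np.argmin(d_ft.min(axis=1)))
                init_dist = float(
                    np.linalg.norm(pos[target_idx] - robot_state.position)
                )
                pending = {
                    "t_trigger": t,
                    "target": target_idx,
                    "goal": pos[target_idx].copy(),
                    "distance": init_dist,
                    "tier": classify_tier(init_dist),
                }
                next_trigger = trigger_times.pop(0) if trigger_times else None
                halting = True  # brake along the curve before engaging

            if phase.name == "idle-patrol":
                # Patrol speed ramps up/down within the 20 cm/s^2 limit;
                # position glides along the stored curve.
                if halting:
                    patrol_speed = max(0.0, patrol_speed - ROBOT_MAX_ACCEL * dt)
                else:
                    patrol_speed = min(PATROL_SPEED, patrol_speed + ROBOT_MAX_ACCEL * dt)
                patrol_pos = (patrol_pos + patrol_speed * dt / seg_len) % len(curve)
                new_p = curve_point(patrol_pos)
                robot_state.velocity = (new_p - robot_state.position) / dt
                if np.linalg.norm(robot_state.velocity) > 1e-9:
                    robot_state.heading = float(
                        math.atan2(robot_state.velocity[1], robot_state.velocity[0])
                    )
                robot_state.position = new_p
                if halting and patrol_speed <= 1e-12:
                    halting = False
                    robot_state.velocity = np.zeros(2)
                    phase = ControllerPhase(name="orient", tier=pending["tier"])
            else:
                # The lunge aims at the target's position at trigger time:
                # the gantry executes a feed-forward move to that point.
                tgt = pending["goal"] if pending is not None else robot_state.position
                robot_state, phase = attack_controller_step(
                    robot_state, tgt, phase, dt, geometry
                )
                if phase.name == "idle-patrol" and pending is not None:
                    attacks.append(
                        AttackEvent(
                            t_trigger=pending["t_trigger"],
                            target_id=agent_ids[pending["target"]],
                            initial_distance=pending["distance"],
                            tier=pending["tier"],
                            t_complete=t + dt,
                        )
                    )
                    pending = None

        # ---- animal update ------------------------------------------------
        hvec = np.stack([np.cos(heading), np.sin(heading)], axis=1)

        # Mosquitofish steering: cohesion + alignment + fear of the robot.
        centroid = pos[fish].mean(axis=0)
        coh = centroid[None, :] - pos[fish]
        coh_n = np.linalg.norm(coh, axis=1, keepdims=True)
        coh = np.where(coh_n > 1e-9, coh / np.maximum(coh_n, 1e-9), 0.0)
        ali = hvec[fish].mean(axis=0)
        w_coh = _FISH_W_COHESION
        des = _FISH_W_PERSIST * hvec[fish] + _FISH_W_ALIGNMENT * ali
        # Zone of repulsion: avoid collisions with close shoal-mates.
        diff = pos[fish][:, None, :] - pos[fish][None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        close = dist < _FISH_SEP_RADIUS
        if close.any():
            push = diff / (dist[:, :, None] ** 2 + 1e-6)
            des += _FISH_W_SEP * (push * close[:, :, None]).sum(axis=1)
        if has_robot and coupling.fish_fear_gain > 0:
            away = pos[fish] - robot_state.position[None, :]
            d_rob = np.linalg.norm(away, axis=1, keepdims=True)
            near = (d_rob[:, 0] < _FISH_FEAR_RADIUS)
            if np.any(near):
                des[near] += (
                    coupling.fish_fear_gain
                    * _FISH_FEAR_WEIGHT
                    * away[near] / np.maximum(d_rob[near], 1e-9)
                )
                w_coh = _FISH_W_COHESION * (1.0 + 0.5 * coupling.fish_fear_gain)
        des += w_coh * coh
        des_angle = np.arctan2(des[:, 1], des[:, 0])
        steer = wrap_angle(des_angle - heading[fish])
        steer = np.clip(steer, -_FISH_MAX_TURN * dt, _FISH_MAX_TURN * dt)

        fish_sigma = _FISH_TURN_SD * (
            1.0 + coupling.fish_from_tadpole_gain * (tad_act_old - 1.0)
        )
        fish_sigma = max(0.2 * _FISH_TURN_SD, fish_sigma)
        noise_fish = fish_sigma * math.sqrt(dt) * rng.standard_normal(n_fish)
        d_heading_fish = steer + noise_fish

        # Tadpole steering: slow correlated random walk; turning noise scales
        # with the fish group's erratic (noise-driven) activity one-to-two
        # windows earlier.
        tad_sigma = _TAD_TURN_SD * (
            1.0 + coupling.tadpole_from_fish_gain * (fish_act_old - 1.0)
        )
        tad_sigma = max(0.2 * _TAD_TURN_SD, tad_sigma)
        noise_tad = tad_sigma * math.sqrt(dt) * rng.standard_normal(n_tadpoles)
        d_heading_tad = noise_tad

        # Activity is accumulated from the stochastic heading component, the
        # erratic darting a responder perceives.
        fish_turn_accum += float(np.mean(np.abs(noise_fish)))
        tad_turn_accum += float(np.mean(np.abs(noise_tad)))
        if (f + 1) % win == 0:
            fish_act_old, fish_act = fish_act, fish_turn_accum / win / fish_turn_base
            tad_act_old, tad_act = tad_act, tad_turn_accum / win / tad_turn_base
            fish_turn_accum = 0.0
            tad_turn_accum = 0.0

        heading[fish] = wrap_angle(heading[fish] + d_heading_fish)
        heading[tads] = wrap_angle(heading[tads] + d_heading_tad)

        # Speed: Ornstein-Uhlenbeck around the species cruise speed.
        speed[fish] += (_FISH_SPEED_MEAN - speed[fish]) * _FISH_SPEED_RELAX * dt \
            + _FISH_SPEED_SD * math.sqrt(dt) * rng.standard_normal(n_fish)
        speed[tads] += (_TAD_SPEED_MEAN - speed[tads]) * _FISH_SPEED_RELAX * dt \
            + _TAD_SPEED_SD * math.sqrt(dt) * rng.standard_normal(n_tadpoles)
        np.clip(speed[fish], 0.2, 15.0, out=speed[fish])
        np.clip(speed[tads], 0.1, 8.0, out=speed[tads])

        pos = pos + np.stack([np.cos(heading), np.sin(heading)], axis=1) * speed[:, None] * dt
        pos, heading = _reflect(pos, heading, r_max)

    return TrialRecording(
        fps=fps,
        duration=duration,
        agent_ids=agent_ids,
        species=species,
        positions=positions,
        headings=headings,
        attacks=attacks,
        treatment=treatment,
        seed=seed,
        coupling=coupling,
        geometry=geometry,
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def cm_to_px(xy: np.ndarray, rc: RenderConfig) -> np.ndarray:
    """Arena-centred cm (y up) -> pixel coordinates (x right, y down)."""
    h, w = rc.image_size
    xy = np.asarray(xy, dtype=float)
    px = np.empty_like(xy)
    px[..., 0] = w / 2.0 + xy[..., 0] / rc.cm_per_pixel
    px[..., 1] = h / 2.0 - xy[..., 1] / rc.cm_per_pixel
    return px


def px_to_cm(px: np.ndarray, rc: RenderConfig) -> np.ndarray:
    """Pixel coordinates (y down) -> arena-centred cm (y up)."""
    h, w = rc.image_size
    px = np.asarray(px, dtype=float)
    xy = np.empty_like(px)
    xy[..., 0] = (px[..., 0] - w / 2.0) * rc.cm_per_pixel
    xy[..., 1] = (h / 2.0 - px[..., 1]) * rc.cm_per_pixel
    return xy


def render_frames(recording: TrialRecording, rc: RenderConfig = RenderConfig(),
                  seed: int = 0) -> RenderResult:
    """Rasterise a trial into noisy grayscale frames.

    Each non-missed agent becomes a disk with its species' area and mean
    intensity on a dark background, plus additive Gaussian noise.  The
    returned ground-truth table maps (frame, agent_id) to the projected pixel
    centroid and a visibility flag, for evaluating the tracker.

    Intended for clips, not full hour-long trials: the stack is held in
    memory (``n_frames x H x W`` bytes).
    """
    import pandas as pd
    from skimage.draw import disk as draw_disk

    rng = np.random.default_rng(seed)
    h, w = rc.image_size
    radii = {}
    for sp, area in rc.species_blob_area.items():
        r = math.sqrt(area / math.pi) / 1.0
        if 2 * r < 1.0:
            raise ValueError(f"blob for {sp} smaller than 1 px across")
        radii[sp] = r

    half_w = (w / 2.0) * rc.cm_per_pixel
    half_h = (h / 2.0) * rc.cm_per_pixel
    if recording.geometry.radius > min(half_w, half_h):
        raise ValueError("arena does not fit in the image at this scale")

    frames = np.empty((recording.n_frames, h, w), dtype=np.uint8)
    rows = []
    for f in range(recording.n_frames):
        img = np.full((h, w), rc.background, dtype=float)
        centres = cm_to_px(recording.positions[f], rc)
        visible = rng.uniform(size=recording.n_agents) >= rc.miss_rate
        for i in range(recording.n_agents):
            sp = recording.species[i]
            if visible[i]:
                rr, cc = draw_disk(
                    (centres[i, 1], centres[i, 0]), radii[sp], shape=(h, w)
                )
                img[rr, cc] = rc.species_intensity[sp]
            rows.append(
                (f, recording.agent_ids[i], sp.value,
                 centres[i, 0], centres[i, 1], bool(visible[i]))
            )
        if rc.noise_sd > 0:
            img += rng.normal(0.0, rc.noise_sd, size=img.shape)
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        rows, columns=["frame", "agent_id", "species", "x_px", "y_px", "visible"]
    )
    return RenderResult(frames=frames, truth=truth, config=rc)
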