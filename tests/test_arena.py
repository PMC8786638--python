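"""Arena simulator: attack scheduling, controller kinematics, trial
invariants and rendering ground truth."""

import math

import numpy as np
import pytest

from ethotrack.arena import (
    MAX_ATTACK_DURATION_S,
    ROBOT_MAX_ACCEL,
    ROBOT_MAX_SPEED,
    AgentState,
    ArenaGeometry,
    AttackEvent,
    ControllerPhase,
    CouplingSpec,
    RenderConfig,
    Species,
    Tier,
    attack_controller_step,
    classify_tier,
    patrol_curve,
    render_frames,
    schedule_attacks,
    simulate_trial,
)

DT = 0.05


def run_attack(start, target, dt=DT, max_steps=2000):
    """Drive the controller from trigger to completion; returns the speed
    profile and the final state."""
    robot = AgentState("robot", Species.ROBOT, np.asarray(start, float), [0, 0], 0.0)
    phase = ControllerPhase(name="orient")
    speeds, positions = [], [robot.position.copy()]
    for _ in range(max_steps):
        robot, phase = attack_controller_step(robot, np.asarray(target, float), phase, dt)
        speeds.append(float(np.linalg.norm(robot.velocity)))
        positions.append(robot.position.copy())
        if phase.name == "idle-patrol":
            break
    return np.array(speeds), np.array(positions), robot, phase


class TestScheduleAttacks:
    def test_hourly_trial_has_fewer_than_sixty_attacks(self):
        for seed in range(10):
            t = schedule_attacks(3600.0, 1.0, None, seed)
            assert 0 < len(t) < 60
            assert len(t) < 3600 / 60 * 1.0 + 1

    def test_zero_duration_yields_no_attacks(self):
        assert len(schedule_attacks(0.0, 1.0, None, 1)) == 0

    def test_standardized_count_is_exact(self):
        t = schedule_attacks(3600.0, 1.0, 55, seed=7)
        assert len(t) == 55
        t56 = schedule_attacks(3600.0, 1.0, 56, seed=7)
        assert len(t56) == 56

    @pytest.mark.parametrize("standardize", [None, 55])
    def test_triggers_increasing_and_separated(self, standardize):
        t = schedule_attacks(3600.0, 1.0, standardize, seed=11)
        assert np.all(np.diff(t) >= MAX_ATTACK_DURATION_S - 1e-9)
        assert np.all(t >= 0) and np.all(t < 3600)

    def test_infeasible_standardization_raises(self):
        with pytest.raises(ValueError):
            schedule_attacks(120.0, 1.0, 55, seed=1)

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            schedule_attacks(3600.0, 0.0, None, 1)


class TestTierClassification:
    @pytest.mark.parametrize(
        "d,tier",
        [(0.5, Tier.CONTACT), (0.99, Tier.CONTACT), (1.0, Tier.INSPECTION),
         (5.0, Tier.INSPECTION), (10.0, Tier.INSPECTION), (10.01, Tier.PURSUIT),
         (30.0, Tier.PURSUIT)],
    )
    def test_thresholds(self, d, tier):
        assert classify_tier(d) == tier

    def test_attack_event_checks_tier_consistency(self):
        with pytest.raises(ValueError):
            AttackEvent(0.0, "fish_0", 0.5, Tier.PURSUIT, 5.0)
        with pytest.raises(ValueError):
            AttackEvent(5.0, "fish_0", 0.5, Tier.CONTACT, 5.0)  # complete <= trigger


class TestAttackController:
    def test_contact_turns_without_translation_and_holds(self):
        robot = AgentState("robot", Species.ROBOT, [0.0, 0.0], [0.0, 0.0], 0.0)
        phase = ControllerPhase(name="orient")
        target = np.array([0.0, 0.5])  # 0.5 cm -> contact tier
        r1, p1 = attack_controller_step(robot, target, phase, DT)
        assert p1.name == "hold"
        assert p1.tier == Tier.CONTACT
        assert np.allclose(r1.position, [0.0, 0.0])
        assert r1.heading == pytest.approx(math.pi / 2)  # turned toward fish
        assert p1.hold_remaining == pytest.approx(1.0)
        # hold for 1 s (20 steps), then restore heading in place
        for _ in range(int(1.0 / DT)):
            r1, p1 = attack_controller_step(r1, target, p1, DT)
        assert p1.name == "idle-patrol"
        assert r1.heading == pytest.approx(0.0)
        assert np.allclose(r1.position, [0.0, 0.0])

    def test_zero_distance_treated_as_contact_heading_unchanged(self):
        robot = AgentState("robot", Species.ROBOT, [2.0, 1.0], [0.0, 0.0], 0.7)
        r1, p1 = attack_controller_step(robot, [2.0, 1.0], ControllerPhase(name="orient"), DT)
        assert p1.tier == Tier.CONTACT
        assert r1.heading == pytest.approx(0.7)
        assert np.allclose(r1.position, [2.0, 1.0])

    def test_pursuit_speed_profile_30cm(self):
        """30-cm pursuit: ramp at 20 cm/s^2 for 1 s, plateau at exactly
        20 cm/s, stop ~1 cm short of the target."""
        speeds, positions, robot, _ = run_attack([-10.0, 0.0], [20.0, 0.0])
        assert speeds.max() == pytest.approx(ROBOT_MAX_SPEED, abs=1e-9)
        accel = np.diff(np.concatenate([[0.0], speeds])) / DT
        assert np.all(np.abs(accel) <= ROBOT_MAX_ACCEL + 1e-6)
        # ramp covers the first second of motion
        first_moving = int(np.nonzero(speeds)[0][0])
        assert speeds[first_moving + 19] == pytest.approx(20.0)
        # returns home after the hold
        assert np.allclose(robot.position, [-10.0, 0.0], atol=1e-6)
        # closest approach to the target is about the standoff
        closest = np.linalg.norm(positions - np.array([20.0, 0.0]), axis=1).min()
        assert closest == pytest.approx(1.0, abs=0.15)

    def test_inspection_tier_short_approach(self):
        speeds, positions, robot, _ = run_attack([0.0, 0.0], [5.0, 0.0])
        assert speeds.max() <= ROBOT_MAX_SPEED + 1e-9
        closest = np.linalg.norm(positions - np.array([5.0, 0.0]), axis=1).min()
        assert closest == pytest.approx(1.0, abs=0.15)
        assert np.allclose(robot.position, [0.0, 0.0], atol=1e-6)

    def test_restores_heading_after_attack(self):
        robot = AgentState("robot", Species.ROBOT, [0.0, 0.0], [0.0, 0.0], -1.1)
        phase = ControllerPhase(name="orient")
        target = np.array([8.0, 3.0])
        for _ in range(2000):
            robot, phase = attack_controller_step(robot, target, phase, DT)
            if phase.name == "idle-patrol":
                break
        assert robot.heading == pytest.approx(-1.1)

    def test_rejects_bad_inputs(self):
        robot = AgentState("robot", Species.ROBOT, [0.0, 0.0], [0.0, 0.0], 0.0)
        with pytest.raises(ValueError):
            attack_controller_step(robot, [50.0, 0.0], ControllerPhase(name="orient"), DT)
        with pytest.raises(ValueError):
            attack_controller_step(robot, [1.0, 0.0], ControllerPhase(name="orient"), 0.0)


class TestSimulateTrial:
    def test_frame_count_matches_fps_times_duration(self, short_trial):
        assert short_trial.n_frames == round(short_trial.fps * short_trial.duration)

    def test_population_and_robot_presence(self, short_trial):
        species = short_trial.species
        assert species.count(Species.MOSQUITOFISH) == 6
        assert species.count(Species.TADPOLE) == 6
        assert species.count(Species.ROBOT) == 1
        rec = simulate_trial(duration=5.0, treatment="non_exposed", seed=0)
        assert Species.ROBOT not in rec.species

    def test_positions_inside_arena(self):
        for seed in (0, 5):
            rec = simulate_trial(duration=60.0, treatment="robot_exposed", seed=seed)
            r = np.linalg.norm(rec.positions, axis=2)
            assert r.max() <= rec.geometry.radius + 1e-9

    def test_same_seed_bit_identical(self):
        a = simulate_trial(duration=30.0, treatment="robot_exposed", seed=5)
        b = simulate_trial(duration=30.0, treatment="robot_exposed", seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)
        assert a.attacks == b.attacks

    def test_robot_speed_and_acceleration_limits_full_trial(self):
        rec = simulate_trial(duration=300.0, treatment="robot_exposed", seed=2)
        ridx = rec.agent_ids.index("robot")
        v = np.diff(rec.positions[:, ridx, :], axis=0) * rec.fps
        speed = np.linalg.norm(v, axis=1)
        assert speed.max() <= ROBOT_MAX_SPEED + 1e-6
        # displacement differencing along the curved patrol path
        # under-measures speed by the chord-arc gap; allow 0.25% for it
        accel = np.abs(np.diff(speed)) * rec.fps
        assert accel.max() <= ROBOT_MAX_ACCEL + 0.05
        assert len(rec.attacks) > 0

    def test_attacks_never_overlap_and_tiers_consistent(self):
        rec = simulate_trial(duration=600.0, treatment="robot_exposed", seed=4)
        prev_complete = -np.inf
        for a in rec.attacks:
            assert a.t_trigger >= prev_complete - 1e-9
            assert a.t_complete > a.t_trigger
            assert a.tier == classify_tier(a.initial_distance)
            prev_complete = a.t_complete

    def test_standardized_attack_log_length(self):
        rec = simulate_trial(duration=600.0, treatment="robot_exposed",
                             seed=8, standardize_attacks=9)
        assert len(rec.attacks) == 9

    def test_inconsistent_fps_duration_raises(self):
        with pytest.raises(ValueError):
            simulate_trial(duration=10.03, fps=20.0, seed=0)


class TestPatrolCurve:
    def test_curve_stays_in_central_region(self):
        c = patrol_curve()
        assert np.linalg.norm(c, axis=1).max() < 15.0

    def test_uniform_arc_length(self):
        c = patrol_curve()
        seg = np.linalg.norm(np.diff(np.vstack([c, c[:1]]), axis=0), axis=1)
        assert seg.max() / seg.min() < 1.01


class TestRenderFrames:
    def test_empty_recording_gives_noise_only_frames(self):
        rec = simulate_trial(duration=0.5, treatment="non_exposed",
                             seed=0, n_fish=0, n_tadpoles=0)
        rc = RenderConfig(noise_sd=2.0)
        res = render_frames(rec, rc, seed=0)
        assert res.frames.shape[0] == 10
        assert res.frames.max() <= rc.background + 6 * rc.noise_sd

    def test_blob_count_conserved_without_misses(self, short_trial, render_config):
        res = render_frames(short_trial, render_config, seed=0)
        from skimage.measure import label

        n_blobs = label(res.frames[0] > 40).max()
        # 13 agents; some blobs may touch, so count cannot exceed 13
        assert 10 <= n_blobs <= 13
        assert len(res.truth[res.truth.frame == 0]) == 13
        assert res.truth.visible.all()

    def test_rendered_centroids_match_projection(self, rendered_clip, render_config):
        """Centroid of each isolated rendered blob lies within 1 px of the
        projected agent position (independent centroid computation)."""
        from skimage.measure import label, regionprops

        frame = rendered_clip.frames[0]
        truth0 = rendered_clip.truth[rendered_clip.truth.frame == 0]
        props = regionprops(label(frame > 40))
        centroids = np.array([[p.centroid[1], p.centroid[0]] for p in props])
        matched = 0
        for _, row in truth0.iterrows():
            p = np.array([row.x_px, row.y_px])
            others = truth0[truth0.agent_id != row.agent_id][["x_px", "y_px"]].to_numpy()
            if np.linalg.norm(others - p, axis=1).min() < 20:
                continue  # skip touching blobs: merged centroid is not the agent's
            d = np.linalg.norm(centroids - p, axis=1).min()
            assert d < 1.0
            matched += 1
        assert matched >= 6

    def test_miss_rate_removes_blobs(self, short_trial):
        rc = RenderConfig(miss_rate=0.5)
        res = render_frames(short_trial, rc, seed=0)
        vis = res.truth.visible.mean()
        assert 0.4 < vis < 0.6

    def test_subpixel_blob_errors(self, short_trial):
        from ethotrack.arena import Species

        rc = RenderConfig(
            species_blob_area={Species.MOSQUITOFISH: 0.5, Species.TADPOLE: 0.3,
                               Species.ROBOT: 0.7}  # all below 1 px across
        )
        with pytest.raises(ValueError):
            render_frames(short_trial, rc, seed=0)

    def test_arena_must_fit_in_image(self, short_trial):
        rc = RenderConfig(image_size=(100, 100), cm_per_pixel=0.1)
        with pytest.raises(ValueError):
            render_frames(short_trial, rc, seed=0)


class TestCouplingSpec:
    def test_rejects_negative_gains(self):
        with pytest.raises(ValueError):
            CouplingSpec(fish_fear_gain=-0.1)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ArenaGeometry(diameter=42.0, ring_width=4.0, n_rings=7)
        with pytest.raises(ValueError):
            ArenaGeometry(central_radius=25.0)
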