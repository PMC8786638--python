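"""Blob detection, species classification, optimal assignment, Kalman
prediction and the full tracking round trip."""

import itertools

import numpy as np
import pytest

from ethotrack.arena import RenderConfig, Species
from ethotrack.tracking import (
    Detection,
    SpeciesCriteria,
    Track,
    assign,
    classify_species,
    default_criteria,
    detect,
    fit_thresholds,
    kalman_step,
    track_trial,
)


@pytest.fixture(scope="module")
def criteria():
    return default_criteria(RenderConfig())


def make_frame(blobs, size=(120, 120), background=10.0, noise_sd=0.0, seed=0):
    """Synthetic frame with square-ish disks: blobs = [(x, y, radius, intensity)]."""
    from skimage.draw import disk

    rng = np.random.default_rng(seed)
    img = np.full(size, background)
    for x, y, r, inten in blobs:
        rr, cc = disk((y, x), r, shape=size)
        img[rr, cc] = inten
    if noise_sd:
        img += rng.normal(0, noise_sd, size)
    return np.clip(img, 0, 255).astype(np.uint8)


class TestDetect:
    def test_blank_noise_frame_yields_nothing(self):
        frame = make_frame([], noise_sd=2.0, seed=1)
        dets = detect(frame, [40.0], (20.0, 400.0))
        assert dets == []

    def test_finds_all_separated_blobs(self):
        frame = make_frame([(20, 20, 5, 130), (60, 60, 3.5, 210), (95, 30, 8.4, 70)])
        dets = detect(frame, [40.0, 100.0, 170.0], (20.0, 400.0))
        assert len(dets) == 3
        for d, (x, y) in zip(
            sorted(dets, key=lambda d: d.centroid[0]), [(20, 20), (60, 60), (95, 30)]
        ):
            pass  # order differs by threshold level; just check coverage below
        found = {tuple(np.round(d.centroid).astype(int)) for d in dets}
        for x, y, *_ in [(20, 20), (60, 60), (95, 30)]:
            assert any(abs(fx - x) <= 1 and abs(fy - y) <= 1 for fx, fy in found)

    def test_small_speck_filtered_by_area(self):
        frame = make_frame([(50, 50, 5, 130)])
        frame[10, 10] = 200
        frame[10, 11] = 200  # 2-px speck
        dets = detect(frame, [40.0], (20.0, 400.0))
        assert len(dets) == 1
        assert np.linalg.norm(dets[0].centroid - [50, 50]) < 1.0

    def test_rendered_frame_recovers_thirteen_agents(self, rendered_clip, criteria):
        th = fit_thresholds(rendered_clip.frames[:3])
        dets = detect(
            rendered_clip.frames[0], th,
            {sp: criteria.area[sp] for sp in criteria.area},
            intensity_bounds=criteria.intensity,
        )
        labeled = classify_species(dets, criteria)
        by_sp = {
            sp: sum(1 for d in labeled if d.species == sp)
            for sp in (Species.MOSQUITOFISH, Species.TADPOLE, Species.ROBOT)
        }
        assert by_sp[Species.MOSQUITOFISH] == 6
        assert by_sp[Species.TADPOLE] == 6
        assert by_sp[Species.ROBOT] == 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            detect(np.zeros((0, 0), dtype=np.uint8), [40.0], (20.0, 400.0))
        with pytest.raises(ValueError):
            detect(np.zeros((10, 10), dtype=np.uint8), [], (20.0, 400.0))
        with pytest.raises(ValueError):
            detect(np.zeros((10, 10), dtype=np.uint8), [300.0], (20.0, 400.0))
        with pytest.raises(ValueError):
            detect(np.zeros((4, 4, 3), dtype=np.uint8), [40.0], (20.0, 400.0))


class TestClassifySpecies:
    def test_unique_interval_match(self, criteria):
        d = Detection(0, [10, 10], area=40.0, mean_intensity=210.0)
        (out,) = classify_species([d], criteria)
        assert out.species == Species.TADPOLE

    def test_no_interval_match_is_unknown(self, criteria):
        d = Detection(0, [10, 10], area=40.0, mean_intensity=130.0)
        (out,) = classify_species([d], criteria)
        assert out.species is None

    def test_robot_blob_identified_by_intensity_band(self, criteria):
        d = Detection(0, [10, 10], area=220.0, mean_intensity=70.0)
        (out,) = classify_species([d], criteria)
        assert out.species == Species.ROBOT

    def test_fully_overlapping_criteria_rejected(self):
        with pytest.raises(ValueError):
            SpeciesCriteria(
                area={Species.MOSQUITOFISH: (10, 50), Species.TADPOLE: (40, 80)},
                intensity={Species.MOSQUITOFISH: (100, 160), Species.TADPOLE: (150, 200)},
            )


class TestAssign:
    def test_diagonal_optimum(self):
        matches, ut, ud = assign([[0, 0], [5, 0]], [[0, 0.1], [5, 0.1]], gate=2.0)
        assert sorted(matches) == [(0, 0), (1, 1)]
        assert ut == [] and ud == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            preds = rng.uniform(0, 50, (n, 2))
            dets = rng.uniform(0, 50, (n, 2))
            cost = np.linalg.norm(preds[:, None] - dets[None, :], axis=2)
            matches, _, _ = assign(preds, dets, gate=np.inf)
            got = sum(cost[r, c] for r, c in matches)
            best = min(
                sum(cost[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_gating_leaves_far_detection_unmatched(self):
        matches, ut, ud = assign([[0, 0]], [[10, 0]], gate=5.0)
        assert matches == []
        assert ut == [0] and ud == [0]

    def test_empty_inputs(self):
        matches, ut, ud = assign(np.empty((0, 2)), np.empty((0, 2)), gate=1.0)
        assert matches == [] and ut == [] and ud == []


class TestKalman:
    # Noise-free cases use vanishing filter noise so the constant-velocity
    # model is the exact data-generating process.
    def test_constant_velocity_extrapolation_is_exact(self):
        tr = Track("a", Species.MOSQUITOFISH)
        for x in (0.0, 1.0, 2.0):
            kalman_step(tr, np.array([x, 0.0]), dt=1.0,
                        process_noise=1e-9, measurement_noise=1e-9)
        kalman_step(tr, None, dt=1.0, process_noise=1e-9, measurement_noise=1e-9)
        assert tr.positions[-1] == pytest.approx([3.0, 0.0], abs=1e-6)
        assert tr.sources[-1] == "predicted"

    def test_stationary_history_predicts_last_position(self):
        tr = Track("a", Species.MOSQUITOFISH)
        for _ in range(5):
            kalman_step(tr, np.array([2.0, -1.0]), dt=0.05,
                        process_noise=1e-9, measurement_noise=1e-9)
        kalman_step(tr, None, dt=0.05, process_noise=1e-9, measurement_noise=1e-9)
        assert tr.positions[-1] == pytest.approx([2.0, -1.0], abs=1e-6)

    def test_filter_reduces_noise_on_linear_motion(self):
        """Filtered MSE beats raw observation MSE over a seeded run."""
        rng = np.random.default_rng(0)
        dt, n, sigma = 0.05, 1000, 0.3
        truth = np.stack([np.linspace(0, 50, n), np.zeros(n)], axis=1)
        obs = truth + rng.normal(0, sigma, (n, 2))
        tr = Track("a", Species.MOSQUITOFISH)
        for z in obs:
            kalman_step(tr, z, dt=dt, process_noise=5.0, measurement_noise=sigma**2)
        est = np.asarray(tr.positions)
        mse_f = np.mean(np.sum((est[100:] - truth[100:]) ** 2, axis=1))
        mse_o = np.mean(np.sum((obs[100:] - truth[100:]) ** 2, axis=1))
        assert mse_f < mse_o

    def test_rejects_nonfinite_observation_and_bad_dt(self):
        tr = Track("a", Species.MOSQUITOFISH)
        kalman_step(tr, np.array([0.0, 0.0]), dt=0.05)
        with pytest.raises(ValueError):
            kalman_step(tr, np.array([np.nan, 0.0]), dt=0.05)
        with pytest.raises(ValueError):
            kalman_step(tr, np.array([0.0, 0.0]), dt=0.0)


class TestTrackTrial:
    def test_round_trip_recovers_species_counts(self, tracked_clip):
        assert len(tracked_clip.by_species(Species.MOSQUITOFISH)) == 6
        assert len(tracked_clip.by_species(Species.TADPOLE)) == 6
        assert len(tracked_clip.by_species(Species.ROBOT)) == 1

    def test_round_trip_positions_within_half_centimetre(
        self, tracked_clip, short_trial
    ):
        from scipy.optimize import linear_sum_assignment

        errs = []
        for sp in (Species.MOSQUITOFISH, Species.TADPOLE):
            est = tracked_clip.positions_of(sp)
            true = short_trial.positions[:, short_trial.species_index(sp), :]
            assert est.shape == true.shape
            for f in range(est.shape[0]):
                c = np.linalg.norm(est[f][:, None] - true[f][None], axis=2)
                r, cidx = linear_sum_assignment(c)
                errs.extend(c[r, cidx])
        errs = np.array(errs)
        assert (errs < 0.5).mean() >= 0.99

    def test_misses_filled_with_predictions(self, short_trial):
        from ethotrack.arena import render_frames

        rc = RenderConfig(miss_rate=0.05)
        res = render_frames(short_trial, rc, seed=5)
        ts = track_trial(res.frames, rc, short_trial.geometry, fps=short_trial.fps)
        n_frames = len(res.frames)
        for tr in ts.tracks:
            assert len(tr.positions) == n_frames
        sources = [s for t in ts.tracks for s in t.sources]
        assert "predicted" in sources

    def test_observed_samples_bounded_by_detections(self, tracked_clip):
        # 13 agents max -> no frame can have more observed samples than that
        per_frame = np.zeros(len(tracked_clip.tracks[0].sources), dtype=int)
        for tr in tracked_clip.tracks:
            per_frame += np.asarray(tr.sources, dtype=object) == "observed"
        assert per_frame.max() <= 13

    def test_empty_stack_gives_empty_trackset(self):
        ts = track_trial([], RenderConfig())
        assert ts.tracks == []

    def test_frame_size_change_raises(self):
        frames = [np.zeros((50, 50), dtype=np.uint8), np.zeros((40, 50), dtype=np.uint8)]
        with pytest.raises(ValueError):
            track_trial(frames, RenderConfig())
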