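"""Orientation angles, hysteresis event detection, rates, Poisson tests."""

import numpy as np
import pytest

from flipscan.scrambling import (
    AngleSeries,
    block_rate,
    classify_events,
    detect_all_events,
    detect_events,
    lipid_orientation_angles,
    poisson_test,
    smooth_angles,
)

from conftest import single_lipid_trajectory


def series_from(theta, dt=1.0, smooth=False):
    theta = np.asarray(theta, dtype=float)
    return AngleSeries(
        lipid_id=1,
        t=np.arange(len(theta)) * dt,
        theta_raw=theta,
        theta_smooth=smooth_angles(theta, dt) if smooth else theta,
    )


class TestAngles:
    @pytest.mark.parametrize(
        "nc3,c4a,c4b,expected",
        [
            ((0, 0, 20), (0, 0, 10), (0, 0, 10), 180.0),  # tails below head
            ((0, 0, 0), (10, 0, 0), (10, 0, 0), 90.0),  # in-plane
            ((0, 0, 0), (1, 0, 1), (-1, 0, 1), 0.0),  # mean vector along +z
        ],
    )
    def test_reference_geometries(self, nc3, c4a, c4b, expected):
        traj = single_lipid_trajectory(nc3, c4a, c4b)
        s = lipid_orientation_angles(traj)[0]
        assert s.theta_raw[0] == pytest.approx(expected, abs=1e-9)

    def test_missing_tail_bead_names_lipid(self):
        traj = single_lipid_trajectory((0, 0, 20), (0, 0, 10), (0, 0, 10))
        traj.names[4] = "C1A"  # demote one terminal bead
        traj.roles[4] = "other"
        with pytest.raises(ValueError, match="7"):
            lipid_orientation_angles(traj)

    def test_centered_window_truncated_at_edges(self):
        x = np.arange(10.0)
        sm = smooth_angles(x, dt=1.0, window_ns=5.0)
        # interior: plain centered mean; edges: truncated window
        assert sm[5] == pytest.approx(np.mean(x[3:8]))
        assert sm[0] == pytest.approx(np.mean(x[:3]))
        assert sm[-1] == pytest.approx(np.mean(x[-3:]))


class TestDetection:
    def test_monotone_flip_single_event(self):
        th = np.linspace(150, 30, 121)
        ev = detect_events(series_from(th))
        assert len(ev) == 1
        assert ev[0].direction == "upper_to_lower"
        assert ev[0].t_complete == float(np.argmax(th < 35))

    def test_partial_transitions_emit_nothing(self):
        one = np.concatenate([np.linspace(150, 50, 20), np.linspace(50, 150, 20)])
        th = np.tile(one, 5)
        assert detect_events(series_from(th)) == []

    def test_oscillating_trace_alternates_three_events(self):
        th = np.concatenate(
            [np.linspace(150, 30, 30), np.linspace(30, 150, 30),
             np.linspace(150, 30, 30)]
        )
        ev = detect_events(series_from(th))
        assert [e.direction for e in ev] == [
            "upper_to_lower", "lower_to_upper", "upper_to_lower"
        ]

    def test_initial_state_from_first_smoothed_angle(self):
        th = np.concatenate([[80.0] * 5, np.linspace(80, 150, 40)])
        ev = detect_events(series_from(th))  # starts "lower" (80 < 90)
        assert [e.direction for e in ev] == ["lower_to_upper"]

    def test_t_enter_band_is_last_origin_band_frame(self):
        th = np.concatenate([[160.0] * 10, np.linspace(160, 20, 50)])
        ev = detect_events(series_from(th))
        # last frame > 145 before completing
        last_in_band = np.flatnonzero(th > 145.0).max()
        assert ev[0].t_enter_band == float(last_in_band)
        assert ev[0].t_enter_band <= ev[0].t_complete

    def test_matches_bruteforce_state_machine_on_random_traces(self):
        rng = np.random.default_rng(11)

        def oracle(th):
            state = "u" if th[0] > 90 else "l"
            out = []
            for f, v in enumerate(th):
                if state == "u" and v < 35.0:
                    out.append(("upper_to_lower", f))
                    state = "l"
                elif state == "l" and v > 145.0:
                    out.append(("lower_to_upper", f))
                    state = "u"
            return out

        for _ in range(1000):
            th = rng.uniform(0.0, 180.0, size=rng.integers(2, 60))
            got = [(e.direction, int(e.t_complete)) for e in
                   detect_events(series_from(th))]
            assert got == oracle(th)

    def test_time_reversal_swaps_directions(self):
        # traces pinned in a pole band at both ends: reversing time must
        # give the same events in reverse order with directions swapped
        swap = {"upper_to_lower": "lower_to_upper",
                "lower_to_upper": "upper_to_lower"}
        rng = np.random.default_rng(3)
        for _ in range(100):
            th = rng.uniform(0, 180, 200)
            th[0] = 160.0 if rng.random() < 0.5 else 20.0
            th[-1] = 160.0 if rng.random() < 0.5 else 20.0
            fwd = detect_events(series_from(th))
            rev = detect_events(series_from(th[::-1]))
            assert [e.direction for e in rev] == [
                swap[e.direction] for e in reversed(fwd)
            ]

    def test_planted_flips_recovered_with_ids_and_directions(self, flip_system):
        _, traj, truth = flip_system
        _, events, _ = detect_all_events(traj)
        assert len(events) == len(truth.events)
        got = sorted((e.lipid_id, e.direction) for e in events)
        want = sorted((e.lipid_id, e.direction) for e in truth.events)
        assert got == want

    def test_classification_totals_partition_events(self, flip_system):
        _, traj, truth = flip_system
        _, events, _ = detect_all_events(traj)
        pw = traj.metadata["pathways"]["groove_axis"]
        classify_events(events, traj, pw)
        n_in = sum(e.pathway_class == "in_groove" for e in events)
        n_out = sum(e.pathway_class == "out_of_groove" for e in events)
        n_un = sum(e.pathway_class == "unclassified" for e in events)
        assert n_in + n_out + n_un == len(events)
        assert n_un == 0

    def test_no_pathway_means_unclassified(self, flip_system):
        _, traj, _ = flip_system
        _, events, _ = detect_all_events(traj)
        classify_events(events, traj, None)
        assert all(e.pathway_class == "unclassified" for e in events)


class TestRates:
    def test_block_rate_arithmetic(self):
        counts = [2, 3, 1, 4, 2, 3, 2, 3, 2]
        times = []
        for b, c in enumerate(counts):
            times.extend(b * 1000.0 + np.linspace(10, 900, c))
        est = block_rate(times, duration=9000.0)
        assert est.per_block_counts == counts
        assert est.mean == pytest.approx(np.sum(counts) / 9.0)
        assert est.sd == pytest.approx(np.std(counts, ddof=0))
        assert est.mean == pytest.approx(
            np.sum(est.per_block_counts) / (est.n_blocks * est.block_length)
        )

    def test_zero_events(self):
        est = block_rate([], duration=5000.0)
        assert est.mean == 0.0 and est.sd == 0.0

    def test_trailing_partial_block_discarded(self):
        est = block_rate([950.0, 1500.0], duration=1700.0)
        assert est.n_blocks == 1
        assert est.per_block_counts == [1]

    def test_too_short_duration_is_error(self):
        with pytest.raises(ValueError):
            block_rate([1.0], duration=500.0)


class TestPoisson:
    def test_exponential_gaps_usually_consistent(self):
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            times = np.cumsum(rng.exponential(100.0, 200))
            res = poisson_test(times, duration=times[-1] + 50.0)
            ok += res.verdict == "consistent"
        assert ok >= 45  # 90%

    def test_periodic_schedule_inconsistent(self):
        times = np.arange(90) * 100.0 + 100.0
        res = poisson_test(times, duration=9100.0)
        assert res.verdict == "inconsistent"
        assert res.dispersion_index < 0.5  # strongly under-dispersed

    def test_single_event_undefined(self):
        assert poisson_test([100.0], duration=1000.0).verdict == "undefined"
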