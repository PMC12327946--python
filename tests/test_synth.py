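"""Generator determinism, planted-event laws, and analytic deformations."""

import numpy as np
import pytest

from flipscan.pathway import straight_pathway
from flipscan.scrambling import detect_all_events, lipid_orientation_angles
from flipscan.synth import (
    DeformationSpec,
    SyntheticSpec,
    TracerTransit,
    build_system,
    apply_deformation,
    plant_flip,
    plant_tracers,
    schedule_poisson_events,
)


class TestDeterminismAndConservation:
    def test_identical_seed_bitwise_identical(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=12, duration=80,
                             flip_rate=20.0, seed=42)
        t1, g1 = build_system(spec)
        t2, g2 = build_system(spec)
        assert np.array_equal(t1.coords, t2.coords)
        assert [e.lipid_id for e in g1.events] == [e.lipid_id for e in g2.events]

    def test_no_nans_constant_bead_count(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=12, duration=120,
                             flip_rate=30.0, partial_excursion_rate=10.0,
                             n_groove_waters=5, seed=1)
        traj, _ = build_system(spec)
        assert np.all(np.isfinite(traj.coords))
        assert traj.coords.shape[1] == traj.n_beads

    def test_static_zero_rate_angles_constant(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=50,
                             jitter_sigma=0.0, lateral_diffusion=0.0, seed=0)
        traj, _ = build_system(spec)
        for s in lipid_orientation_angles(traj):
            assert np.ptp(s.theta_raw) < 1e-9

    def test_overcrowded_box_rejected(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=500, box=(60.0, 60.0, 100.0))
        with pytest.raises(ValueError, match="box area"):
            build_system(spec)


class TestPoissonScheduling:
    def test_mean_count_matches_rate(self):
        """flip scheduling is a homogeneous Poisson process: over 50 seeds
        at 10 events/us for 10 us, the mean count is within 3*sqrt(100/50)
        of 100."""
        counts = [
            len(schedule_poisson_events(10.0, 10000.0, np.random.default_rng(s)))
            for s in range(50)
        ]
        assert abs(np.mean(counts) - 100.0) < 3.0 * np.sqrt(100.0 / 50.0)

    def test_zero_rate_empty(self):
        assert len(schedule_poisson_events(0.0, 1000.0,
                                           np.random.default_rng(0))) == 0

    def test_planted_count_equals_ground_truth(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=24, duration=500,
                             flip_rate=15.0, seed=9)
        traj, truth = build_system(spec)
        _, events, _ = detect_all_events(traj)
        assert len(events) == len(truth.events)


class TestPlantFlip:
    def test_complete_flip_crosses_threshold(self, flip_system):
        _, traj, truth = flip_system
        series, events, _ = detect_all_events(traj)
        by_id = {s.lipid_id: s for s in series}
        for ev in truth.events:
            s = by_id[ev.lipid_id]
            if ev.direction == "upper_to_lower":
                assert s.theta_smooth[-1] < 35.0
            else:
                assert s.theta_smooth[-1] > 145.0

    def test_partial_excursion_enters_band_and_returns(self, flip_system):
        _, traj, truth = flip_system
        series = lipid_orientation_angles(traj)
        by_id = {s.lipid_id: s for s in series}
        flipped = {e.lipid_id for e in truth.events}
        for lid, _ in truth.partials:
            if lid in flipped:
                continue
            s = by_id[lid]
            start_upper = s.theta_smooth[0] > 90
            if start_upper:
                assert s.theta_smooth.min() < 145.0  # entered the band
                assert s.theta_smooth.min() >= 45.0  # but never near completion
            else:
                assert s.theta_smooth.max() > 35.0
                assert s.theta_smooth.max() <= 135.0

    def test_groove_flip_labeled_in_groove(self, flip_system):
        _, _, truth = flip_system
        assert all(e.label == "in_groove" for e in truth.events)

    def test_cleft_flip_labeled_out_of_groove(self):
        spec = SyntheticSpec(
            n_lipids_per_leaflet=16, duration=300,
            flip_schedule=((50.0, "dimer_cleft", True),), seed=2,
        )
        _, truth = build_system(spec)
        assert [e.label for e in truth.events] == ["out_of_groove"]

    def test_overlapping_flips_rejected(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=400, seed=0)
        traj, _ = build_system(spec)
        lid = int(traj.lipid_resids()[0])
        pw = traj.metadata["pathways"]["groove_axis"]
        plant_flip(traj, lid, 50.0, pw, 100.0)
        with pytest.raises(ValueError, match="overlap"):
            plant_flip(traj, lid, 100.0, pw, 100.0)


class TestDeformation:
    def test_zero_amplitude_keeps_bulk(self):
        d = DeformationSpec("gaussian_pinch", amplitude=0.0)
        assert d.analytic_min_thickness(30.0) == 30.0

    def test_gaussian_closed_form(self):
        d = DeformationSpec("gaussian_pinch", amplitude=9.0, width=10.0)
        assert d.analytic_min_thickness(30.0) == pytest.approx(12.0)

    def test_sinusoid_matches_brute_force_minimization(self):
        d = DeformationSpec("sinusoid", amplitude=7.0, wavelength=40.0)
        x = np.arange(-60.0, 60.0, 0.01)
        xy = np.column_stack([x, np.zeros_like(x)])
        upper = 15.0 - d.depth(xy)
        lower = -15.0 + d.depth(xy)
        brute = (upper - lower).min()  # symmetric field: closest pair vertical
        assert d.analytic_min_thickness(30.0) == pytest.approx(brute, abs=1e-6)

    def test_apply_deformation_post_hoc(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=16, duration=30,
                             jitter_sigma=0.0, lateral_diffusion=0.0, seed=0)
        traj, _ = build_system(spec)
        d = DeformationSpec("gaussian_pinch", amplitude=5.0, width=15.0)
        traj, mt = apply_deformation(traj, d)
        assert mt == pytest.approx(20.0)
        gl = traj.select(role="lipid_glycerol")
        z = traj.coords[0, gl, 2]
        # beads exist strictly inside +/-15 now
        assert np.abs(z).min() < 15.0 - 1.0

    def test_amplitude_over_half_thickness_rejected(self):
        spec = SyntheticSpec(
            deformation=DeformationSpec("gaussian_pinch", amplitude=16.0)
        )
        with pytest.raises(ValueError, match="amplitude"):
            spec.validate()


class TestTracers:
    def test_planted_counts_recorded(self):
        tr = tuple(
            [TracerTransit("Na", 100.0 + 20 * i, "up") for i in range(10)]
            + [TracerTransit("Cl", 350.0 + 20 * i, "up") for i in range(5)]
        )
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=600,
                             tracer_spec=tr, seed=4)
        _, truth = build_system(spec)
        assert truth.planted_crossings["Na"] == {"up": 10, "down": 0}
        assert truth.planted_crossings["Cl"] == {"up": 5, "down": 0}

    def test_decoy_never_counted_and_schedule_reproducible(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=300,
                             n_decoy_tracers=10, seed=4)
        t1, g1 = build_system(spec)
        t2, _ = build_system(spec)
        assert g1.planted_crossings == {}
        assert np.array_equal(t1.coords, t2.coords)

    def test_post_hoc_plant_tracers_appends_beads(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=200, seed=0)
        traj, _ = build_system(spec)
        n0 = traj.n_beads
        pw = straight_pathway(0.0, 0.0, -27.0, 27.0)
        traj, truth = plant_tracers(
            traj, [TracerTransit("water", 100.0, "down")], pw,
            rng=np.random.default_rng(1), n_decoys=3,
        )
        assert traj.n_beads == n0 + 4
        assert truth.planted_crossings["water"] == {"up": 0, "down": 1}
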