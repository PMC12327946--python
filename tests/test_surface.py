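"""Leaflet surface reconstruction and minimal-thickness extraction."""

import numpy as np
import pytest

from flipscan.scrambling import detect_all_events
from flipscan.surface import (
    SurfacePair,
    assign_leaflets,
    average_surfaces,
    minimal_thickness,
)
from flipscan.synth import DeformationSpec, SyntheticSpec, build_system


def surfaces_for(spec):
    traj, truth = build_system(spec)
    _, events, states = detect_all_events(traj)
    labels = assign_leaflets(traj, states)
    return traj, truth, events, labels, average_surfaces(traj, labels)


def make_pair(upper_z, lower_z, spacing=1.0):
    upper_z = np.asarray(upper_z, dtype=float)
    lower_z = np.asarray(lower_z, dtype=float)
    ones = np.ones_like(upper_z, dtype=bool)
    return SurfacePair(
        origin=np.zeros(2), spacing=spacing,
        upper_z=upper_z, lower_z=lower_z,
        occupancy_upper=np.ones_like(upper_z),
        occupancy_lower=np.ones_like(lower_z),
        mask_upper=ones, mask_lower=ones.copy(),
    )


class TestLeafletAssignment:
    def test_static_bilayer_labels_match_geometry(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=50, seed=0)
        traj, _, _, labels, _ = surfaces_for(spec)
        gl_z = {}
        for i, lid in enumerate(labels.lipid_ids):
            gl = traj.select(resid=int(lid), role="lipid_glycerol")
            gl_z[i] = traj.coords[0, gl, 2].mean()
        for i, lid in enumerate(labels.lipid_ids):
            want = 1 if gl_z[i] > 0 else -1
            assert np.all(labels.labels[i] == want)

    def test_flip_switches_label_at_detected_completion(self, flip_system):
        _, traj, truth = flip_system
        _, events, states = detect_all_events(traj)
        labels = assign_leaflets(traj, states)
        idx = {int(l): i for i, l in enumerate(labels.lipid_ids)}
        for ev in events:
            row = labels.labels[idx[ev.lipid_id]]
            f = int(round(ev.t_complete / traj.dt))
            before, after = row[f - 1], row[f]
            assert before != after  # label switch exactly at t_complete

    def test_scrambling_lipid_never_in_both_leaflets(self, flip_system):
        # labels are a single value per (lipid, frame) by construction of
        # the state machine; the binning respects them exclusively
        _, traj, _ = flip_system
        _, _, states = detect_all_events(traj)
        assert set(np.unique(states)) <= {-1, 1}


class TestAverageSurfaces:
    def test_flat_zero_jitter_exact_heights(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=64, box=(80, 80, 100),
                             duration=40, jitter_sigma=0.0,
                             lateral_diffusion=0.0, seed=1)
        _, _, _, _, sp = surfaces_for(spec)
        assert np.allclose(sp.upper_z[sp.mask_upper], 15.0, atol=1e-9)
        assert np.allclose(sp.lower_z[sp.mask_lower], -15.0, atol=1e-9)

    def test_low_occupancy_cells_discarded_in_bin_mode(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=64, box=(80, 80, 100),
                             duration=500, lateral_diffusion=0.0, seed=2)
        traj, truth = build_system(spec)
        # one lipid's glycerols teleported to a remote corner for 1 frame
        lid = int(traj.lipid_resids()[0])
        gl = traj.select(resid=lid, role="lipid_glycerol")
        traj.coords[250, gl, 0] = 38.5
        traj.coords[250, gl, 1] = 38.5
        _, _, states = detect_all_events(traj)
        sp = average_surfaces(traj, assign_leaflets(traj, states),
                              method="bin")
        ii = int((38.5 - sp.origin[0]) // sp.spacing)
        jj = int((38.5 - sp.origin[1]) // sp.spacing)
        assert sp.occupancy_upper[ii, jj] <= 0.01
        assert not sp.mask_upper[ii, jj]

    def test_interpolation_mode_full_coverage_and_flat_recovery(self):
        # per-frame Delaunay interpolation covers (almost) every cell each
        # frame and averages to a very quiet flat field
        spec = SyntheticSpec(n_lipids_per_leaflet=52, box=(60, 60, 100),
                             duration=150, seed=6)
        traj, _ = build_system(spec)
        _, _, states = detect_all_events(traj)
        sp = average_surfaces(traj, assign_leaflets(traj, states),
                              method="interpolate")
        assert sp.occupancy_upper[sp.mask_upper].min() > 0.9
        assert np.abs(sp.upper_z[sp.mask_upper] - 15.0).max() < 0.5

    def test_gaussian_pinch_height_field_recovered(self):
        spec = SyntheticSpec(
            n_lipids_per_leaflet=205, box=(120, 120, 100), duration=1500,
            deformation=DeformationSpec("gaussian_pinch", amplitude=9.0,
                                        width=12.0),
            seed=3,
        )
        traj, _, _, _, sp = surfaces_for(spec)
        d = traj.metadata["deformation"]
        ii, jj = np.nonzero(sp.mask_upper)
        x = sp.origin[0] + (ii + 0.5) * sp.spacing
        y = sp.origin[1] + (jj + 0.5) * sp.spacing
        want = 15.0 - d.depth(np.column_stack([x, y]))
        err = np.abs(sp.upper_z[ii, jj] - want)
        assert err.max() <= 1.0

    def test_bulk_thickness_recovered_far_from_pinch(self):
        spec = SyntheticSpec(
            n_lipids_per_leaflet=205, box=(120, 120, 100), duration=1500,
            deformation=DeformationSpec("gaussian_pinch", amplitude=9.0,
                                        width=10.0),
            seed=4,
        )
        _, _, _, _, sp = surfaces_for(spec)
        both = sp.mask_upper & sp.mask_lower
        ii, jj = np.nonzero(both)
        r = np.hypot(sp.origin[0] + (ii + 0.5), sp.origin[1] + (jj + 0.5))
        far = r > 40.0  # > 4 widths from the pinch center
        gap = sp.upper_z[ii, jj][far] - sp.lower_z[ii, jj][far]
        assert np.abs(gap - 30.0).max() <= 1.0

    def test_connectivity_filter_keeps_single_component(self):
        from scipy import ndimage

        spec = SyntheticSpec(n_lipids_per_leaflet=64, box=(80, 80, 100),
                             duration=300, seed=5)
        _, _, _, _, sp = surfaces_for(spec)
        for mask in (sp.mask_upper, sp.mask_lower):
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n == 1


class TestMinimalThickness:
    def test_flat_pair_is_bulk(self):
        sp = make_pair(np.full((9, 9), 15.0), np.full((9, 9), -15.0))
        mt = minimal_thickness(sp)
        assert mt.value == pytest.approx(30.0)
        assert mt.value == pytest.approx(
            np.linalg.norm(mt.point_upper - mt.point_lower)
        )

    def test_matches_bruteforce_all_pairs_on_rough_surfaces(self):
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = rng.integers(20, 100)
            up = np.full((n, n), 15.0) + rng.normal(0, 2.0, (n, n))
            lo = np.full((n, n), -15.0) + rng.normal(0, 2.0, (n, n))
            sp = make_pair(up, lo)
            got = minimal_thickness(sp)
            brute = cdist(sp.cell_points("upper"), sp.cell_points("lower")).min()
            assert got.value == pytest.approx(brute, abs=1e-9)

    def test_oblique_minimum_beats_vertical(self):
        # a step edge: the closest pair is diagonal, not vertical
        up = np.full((10, 10), 15.0)
        up[5:] = 2.0
        lo = np.full((10, 10), -15.0)
        lo[:5] = -2.0
        sp = make_pair(up, lo)
        mt = minimal_thickness(sp)
        # diagonal neighbor pair: sqrt(1^2 + 4^2); vertical pairs are >= 17
        assert mt.value == pytest.approx(np.sqrt(17.0))
        assert not np.allclose(mt.point_upper[:2], mt.point_lower[:2])

    def test_deeper_pinch_strictly_thinner(self):
        values = []
        for amp in (3.0, 6.0, 9.0):
            x = np.arange(-20.0, 20.0)
            X, Y = np.meshgrid(x, x, indexing="ij")
            depth = amp * np.exp(-(X**2 + Y**2) / (2 * 10.0**2))
            sp = make_pair(15.0 - depth, -15.0 + depth)
            values.append(minimal_thickness(sp).value)
        assert values[0] > values[1] > values[2]

    def test_region_restriction(self):
        up = np.full((40, 40), 15.0)
        lo = np.full((40, 40), -15.0)
        up[2, 2] = 0.5  # remote dimple dominates the global minimum
        lo[2, 2] = -0.5
        sp = make_pair(up, lo)
        assert minimal_thickness(sp).value == pytest.approx(1.0)
        local = minimal_thickness(sp, region_center=(30.0, 30.0),
                                  region_radius=8.0)
        assert local.value == pytest.approx(30.0)

    def test_empty_mask_is_error(self):
        sp = make_pair(np.full((4, 4), 15.0), np.full((4, 4), -15.0))
        sp.mask_lower[:] = False
        with pytest.raises(ValueError, match="empty"):
            minimal_thickness(sp)
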