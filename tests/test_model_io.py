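"""Trajectory model, format I/O, alignment and equilibration trimming."""

import numpy as np
import pytest

from flipscan.io import (
    align_subunit,
    discard_equilibration,
    load_trajectory,
    write_trajectory,
)
from flipscan.model import SubunitSpec, UnknownBeadError, resolve_roles
from flipscan.synth import SyntheticSpec, build_system

from conftest import make_trajectory


class TestRoles:
    def test_default_martini_table(self):
        names = ["NC3", "PO4", "GL1", "C4A", "BB", "SC1", "W", "NA", "CL"]
        resnames = ["DOPC"] * 4 + ["LEU", "LEU", "W", "NA", "CL"]
        roles = resolve_roles(names, resnames)
        assert list(roles) == [
            "lipid_head", "lipid_phosphate", "lipid_glycerol",
            "lipid_tail_terminal", "protein", "protein", "water",
            "ion_cation", "ion_anion",
        ]

    def test_unknown_bead_is_hard_error_naming_offender(self):
        with pytest.raises(UnknownBeadError, match="XYZ"):
            resolve_roles(["NC3", "XYZ"], ["DOPC", "FOO"])

    def test_user_override_and_qualified_keys(self):
        roles = resolve_roles(
            ["XYZ", "NC3"], ["FOO", "SPEC"],
            role_map={"XYZ": "other", "SPEC:NC3": "water"},
        )
        assert list(roles) == ["other", "water"]


@pytest.fixture(scope="module")
def tiny_system():
    spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=5, seed=6)
    return build_system(spec)[0]


class TestRoundTrip:
    def test_pdb_xtc_round_trip(self, tiny_system, tmp_path):
        top, trj = tmp_path / "s.pdb", tmp_path / "t.xtc"
        write_trajectory(tiny_system, top, trj)
        back = load_trajectory(top, trj)
        assert back.n_beads == tiny_system.n_beads
        assert back.n_frames == tiny_system.n_frames
        assert back.dt == pytest.approx(tiny_system.dt)
        # XTC stores 0.001 nm precision
        assert np.abs(back.coords - tiny_system.coords).max() < 0.02
        assert list(back.names) == list(tiny_system.names)
        assert list(back.roles) == list(tiny_system.roles)
        assert sorted(set(back.chains)) == sorted(set(tiny_system.chains))

    def test_cross_format_consistency(self, tiny_system, tmp_path):
        """The same coordinates written as PDB+XTC and GRO+DCD read back
        identically within format precision."""
        write_trajectory(tiny_system, tmp_path / "s.pdb", tmp_path / "t.xtc")
        write_trajectory(tiny_system, tmp_path / "s.gro", tmp_path / "t.dcd")
        a = load_trajectory(tmp_path / "s.pdb", tmp_path / "t.xtc")
        b = load_trajectory(tmp_path / "s.gro", tmp_path / "t.dcd", dt=1.0)
        assert np.abs(a.coords - b.coords).max() < 0.03
        assert b.dt == 1.0

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_trajectory(tmp_path / "nope.pdb")


class TestAlignment:
    @pytest.fixture()
    def spec_a(self):
        return SubunitSpec("A", ((327, 339), (430, 452)))

    def test_pure_translation_inverted(self, tiny_system, spec_a):
        tr = tiny_system.copy()
        for f in range(1, tr.n_frames):
            tr.coords[f] = tr.coords[0] + [5.0 * f, 0.0, 0.0]
        al = align_subunit(tr, spec_a)
        assert np.abs(al.coords - al.coords[0]).max() < 1e-6

    def test_pure_rotation_inverted(self, tiny_system, spec_a):
        tr = tiny_system.copy()
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        for f in range(1, tr.n_frames):
            tr.coords[f] = tr.coords[0] @ np.linalg.matrix_power(rot90, f).T
        al = align_subunit(tr, spec_a)
        idx = spec_a.resolve(al)
        rmsd = np.sqrt(
            ((al.coords[:, idx] - al.coords[0, idx]) ** 2).sum(-1).mean(-1)
        )
        assert rmsd.max() < 1e-6

    def test_matches_kabsch_oracle_under_jitter(self, tiny_system, spec_a):
        rng = np.random.default_rng(5)
        tr = tiny_system.copy()
        # random rigid motion + per-bead jitter on the selection
        from scipy.spatial.transform import Rotation

        for f in range(1, tr.n_frames):
            R = Rotation.random(random_state=rng).as_matrix()
            tr.coords[f] = (
                tiny_system.coords[0] @ R.T
                + rng.uniform(-10, 10, 3)
                + rng.normal(0, 0.5, tiny_system.coords[0].shape)
            )
        al = align_subunit(tr, spec_a)
        idx = spec_a.resolve(tr)

        def kabsch_rmsd(P, Q):
            Pc = P - P.mean(0)
            Qc = Q - Q.mean(0)
            H = Pc.T @ Qc
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            return np.sqrt(((Pc @ R.T - Qc) ** 2).sum(1).mean())

        for f in range(1, tr.n_frames):
            got = np.sqrt(
                ((al.coords[f, idx] - al.coords[0, idx]) ** 2).sum(1).mean()
            )
            want = kabsch_rmsd(tr.coords[f, idx], tr.coords[0, idx])
            assert got == pytest.approx(want, abs=1e-8)

    def test_idempotent(self, tiny_system, spec_a):
        rng = np.random.default_rng(2)
        tr = tiny_system.copy()
        for f in range(1, tr.n_frames):
            tr.coords[f] += rng.normal(0, 1.0, tr.coords[f].shape)
        once = align_subunit(tr, spec_a)
        twice = align_subunit(once, spec_a)
        assert np.abs(once.coords - twice.coords).max() < 1e-9

    def test_collinear_selection_rejected(self):
        names = ["BB"] * 5 + ["NC3"]
        resnames = ["LEU"] * 5 + ["DOPC"]
        coords = np.zeros((2, 6, 3))
        coords[:, :5, 2] = np.arange(5)  # a straight line
        tr = make_trajectory(names, resnames, coords,
                             resids=[1, 2, 3, 4, 5, 10])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            align_subunit(tr, SubunitSpec("A", ((1, 5),)))

    def test_too_small_selection_rejected(self, tiny_system):
        with pytest.raises(ValueError, match="at least 3"):
            align_subunit(tiny_system, SubunitSpec("A", ((327, 327),)))


class TestEquilibration:
    @pytest.fixture()
    def traj(self):
        spec = SyntheticSpec(n_lipids_per_leaflet=8, duration=100, seed=0)
        return build_system(spec)[0]

    def test_trim_counts_and_t0(self, traj):
        out = discard_equilibration(traj, 10.0)
        assert out.n_frames == traj.n_frames - 10
        assert out.t0 == pytest.approx(10.0)

    def test_zero_is_identity(self, traj):
        out = discard_equilibration(traj, 0.0)
        assert out.n_frames == traj.n_frames
        assert np.array_equal(out.coords, traj.coords)

    def test_trimming_composes(self, traj):
        a = discard_equilibration(discard_equilibration(traj, 10.0), 15.0)
        b = discard_equilibration(traj, 25.0)
        assert a.n_frames == b.n_frames
        assert a.t0 == pytest.approx(b.t0)
        assert np.array_equal(a.coords, b.coords)

    def test_full_trim_is_error(self, traj):
        with pytest.raises(ValueError):
            discard_equilibration(traj, traj.duration)
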