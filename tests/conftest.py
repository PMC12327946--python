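"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from flipscan.model import Trajectory, resolve_roles
from flipscan.synth import SyntheticSpec, build_system


def make_trajectory(names, resnames, coords, resids=None, chains=None,
                    dt=1.0, box=(100.0, 100.0, 100.0)):
    """Hand-build a Trajectory from bead names and a coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    names = np.asarray(names, dtype="U8")
    resnames = np.asarray(resnames, dtype="U8")
    if resids is None:
        resids = np.arange(1, n + 1)
    if chains is None:
        chains = np.full(n, "A", dtype="U4")
    return Trajectory(
        names=names,
        resids=np.asarray(resids, dtype=int),
        resnames=resnames,
        chains=np.asarray(chains, dtype="U4"),
        roles=resolve_roles(names, resnames),
        coords=coords,
        dt=dt,
        box=np.asarray(box, dtype=float),
    )


def single_lipid_trajectory(nc3, c4a, c4b, n_frames=1):
    """One DOPC lipid with only the beads the angle analysis needs plus
    fillers, at fixed positions."""
    po4 = np.asarray(nc3) + [0.0, 0.0, -1.0]
    gl = np.asarray(nc3) + [0.0, 0.0, -2.0]
    coords = np.tile(
        np.asarray([nc3, po4, gl, gl, c4a, c4b], dtype=float), (n_frames, 1, 1)
    )
    return make_trajectory(
        names=["NC3", "PO4", "GL1", "GL2", "C4A", "C4B"],
        resnames=["DOPC"] * 6,
        resids=[7] * 6,
        chains=["M"] * 6,
        coords=coords,
    )


@pytest.fixture(scope="session")
def flip_system():
    """1.2 us system with 5 complete in-groove flips and 5 partials."""
    sched = tuple(
        [(50 + 200 * i, "groove_axis", True) for i in range(5)]
        + [(150 + 200 * i, "groove_axis", False) for i in range(5)]
    )
    spec = SyntheticSpec(
        n_lipids_per_leaflet=32, duration=1200, flip_schedule=sched, seed=3
    )
    traj, truth = build_system(spec)
    return spec, traj, truth
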