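"""Reading and writing standard structure/trajectory formats.

Backed by MDAnalysis for PDB/GRO topologies and XTC/TRR/DCD trajectories.
Everything is converted to the internal angstrom/ns unit system on load.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .model import SubunitSpec, Trajectory, resolve_roles

PS_PER_NS = 1000.0


def load_trajectory(
    topology_path: str | os.PathLike,
    trajectory_path: str | os.PathLike | None = None,
    role_map: Mapping[str, str] | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a topology (+ optional trajectory) into a :class:`Trajectory`.

    Parameters
    ----------
    topology_path, trajectory_path
        PDB or GRO topology; XTC, TRR or DCD coordinates.  With no
        trajectory the topology's single frame is used.
    role_map
        Extra/overriding bead-name -> role entries merged over the default
        Martini 3 table.  Unknown bead names are a hard error.
    dt
        Explicit frame spacing in ns; overrides whatever clock the
        trajectory carries.  Needed for formats without reliable time
        stamps (DCD).
    """
    import MDAnalysis as mda

    for p in (topology_path, trajectory_path):
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(str(p))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(trajectory_path))

    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype="U8")
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    resnames = np.array([a.resname for a in u.atoms], dtype="U8")
    if hasattr(u.atoms, "chainIDs"):
        chains = np.array(
            [c if c.strip() else "A" for c in u.atoms.chainIDs], dtype="U4"
        )
    else:
        chains = np.array(
            [s if s and s != "SYSTEM" else "A" for s in u.atoms.segids], dtype="U4"
        )
    roles = resolve_roles(names, resnames, role_map)

    frames = []
    boxes = []
    times_ps = []
    for ts in u.trajectory:
        if len(ts.positions) != n:
            raise ValueError(
                f"frame {ts.frame}: {len(ts.positions)} coordinates for {n} beads"
            )
        frames.append(ts.positions.astype(np.float64))  # MDAnalysis uses angstrom
        boxes.append(ts.dimensions[:3] if ts.dimensions is not None else None)
        times_ps.append(ts.time)
    coords = np.stack(frames)
    if boxes[0] is None or not np.all(np.asarray(boxes[0]) > 0):
        box = np.full((len(frames), 3), np.nan)
        span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
        box[:] = np.maximum(span, 1.0)
    else:
        box = np.stack([np.asarray(b, dtype=float) for b in boxes])

    times_ns = np.asarray(times_ps) / PS_PER_NS
    if dt is not None:
        # explicit spacing wins; formats like DCD carry no reliable clock
        frame_dt = float(dt)
        t0 = 0.0
    elif len(times_ns) > 1 and np.all(np.diff(times_ns) > 0):
        frame_dt = float(np.median(np.diff(times_ns)))
        t0 = float(times_ns[0])
    else:
        frame_dt = 1.0
        t0 = 0.0

    return Trajectory(
        names=names,
        resids=resids,
        resnames=resnames,
        chains=chains,
        roles=roles,
        coords=coords,
        dt=frame_dt,
        box=box,
        t0=t0,
    )


def write_trajectory(
    traj: Trajectory,
    topology_path: str | os.PathLike,
    trajectory_path: str | os.PathLike | None = None,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the topology (frame 0) and optionally all frames.

    Topology format follows the file extension (.pdb or .gro); trajectory
    likewise (.xtc, .trr, .dcd).  ``bfactors`` (one value per bead) are
    stored in the PDB B-factor column, which is how per-residue dwell
    times are exported for structure coloring.
    """
    import MDAnalysis as mda

    n = traj.n_beads
    resid_keys = {}
    for ri, ch in zip(traj.resids, traj.chains):
        resid_keys.setdefault((str(ch), int(ri)), len(resid_keys))
    n_res = len(resid_keys)
    res_index = np.array(
        [resid_keys[(str(c), int(r))] for c, r in zip(traj.chains, traj.resids)]
    )
    res_order = sorted(resid_keys, key=resid_keys.get)
    segs = sorted({str(c) for c in traj.chains})
    seg_lookup = {s: i for i, s in enumerate(segs)}
    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        n_segments=len(segs),
        atom_resindex=res_index,
        residue_segindex=[seg_lookup[k[0]] for k in res_order],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in traj.names])
    u.add_TopologyAttr("resids", [r for _, r in res_order])
    resname_by_key = {}
    for rn, c, r in zip(traj.resnames, traj.chains, traj.resids):
        resname_by_key.setdefault((str(c), int(r)), str(rn))
    u.add_TopologyAttr("resnames", [resname_by_key[k] for k in res_order])
    u.add_TopologyAttr("chainIDs", [str(c) for c in traj.chains])
    u.add_TopologyAttr("segids", segs)
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    if bfactors is not None:
        u.atoms.tempfactors = np.asarray(bfactors, dtype=float)
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.box[0], 90.0, 90.0, 90.0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=n) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coords[f]
                    u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = (traj.t0 + f * traj.dt) * PS_PER_NS
                    u.trajectory.ts.frame = f
                    w.write(u.atoms)


def align_subunit(traj: Trajectory, spec: SubunitSpec) -> Trajectory:
    """Rigid-body superposition of every frame onto frame 0.

    The optimal (least-squares) rotation + translation for the reference
    selection is found per frame and applied to *all* beads, so lipid,
    water and ion coordinates end up in the protein-fixed frame.  Frame 0
    is left untouched.  Idempotent by construction.
    """
    idx = spec.resolve(traj)
    ref = traj.coords[0, idx]
    ref_c = ref.mean(axis=0)
    ref0 = ref - ref_c
    # collinear selections leave the rotation about the line undetermined
    if np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) alignment selection")

    out = traj.copy()
    for f in range(1, traj.n_frames):
        mob = traj.coords[f, idx]
        mob_c = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref0, mob - mob_c)
        out.coords[f] = (traj.coords[f] - mob_c) @ rot.as_matrix().T + ref_c
    aligned = set(out.metadata.get("aligned_chains", ()))
    aligned.add(spec.chain_id)
    out.metadata["aligned_chains"] = tuple(sorted(aligned))
    return out


def discard_equilibration(traj: Trajectory, t_eq: float) -> Trajectory:
    """Drop the first ``t_eq`` ns (measured from the trajectory start)."""
    if t_eq < 0:
        raise ValueError("t_eq must be >= 0")
    if t_eq >= traj.duration:
        raise ValueError(
            f"t_eq = {t_eq} ns >= trajectory duration {traj.duration} ns"
        )
    n_skip = int(np.ceil(t_eq / traj.dt - 1e-9))
    return traj.slice_frames(n_skip)


# -- small tabular/JSON helpers used by several stages -------------------

def write_json(obj, path: str | os.PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)
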