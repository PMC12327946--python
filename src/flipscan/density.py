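"""3D bead-density grids and maximum-density pathway extraction.

Densities (lipid headgroups, water, ions) are accumulated on a 0.5 A grid
in a protein-fixed frame (the trajectory must have been aligned per
subunit first).  The membrane-spanning maximum-density pathway is traced
slab by slab in z: in each slab the densest cell within a tube radius of
the previous node is picked and refined to the density-weighted centroid
of its 3x3 in-plane neighborhood, giving a connected, z-monotone
polyline.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

from .model import Trajectory
from .pathway import Pathway

GRID_SPACING = 0.5  # angstrom
GRID_SHAPE_A = (100.0, 100.0, 150.0)  # angstrom extents


@dataclasses.dataclass
class DensityGrid:
    origin: np.ndarray  # (3,) corner of the grid, angstrom
    spacing: float
    counts: np.ndarray  # (nx, ny, nz)
    n_frames: int
    n_chains: int = 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def cell_centers_z(self) -> np.ndarray:
        return self.origin[2] + (np.arange(self.shape[2]) + 0.5) * self.spacing


def accumulate_density(
    traj: Trajectory,
    role: str | list[str],
    center: tuple[float, float, float] | None = None,
    extents: tuple[float, float, float] = GRID_SHAPE_A,
    spacing: float = GRID_SPACING,
    check_alignment: bool = True,
    name: str | list[str] | None = None,
) -> DensityGrid:
    """Histogram selected beads over all frames into one grid.

    ``center`` defaults to the midpoint of the TM4/TM6 centroid stored by
    the synthetic builder (the groove center), or the coordinate origin.
    Refuses unaligned trajectories unless ``check_alignment`` is off,
    since densities in a drifting frame are meaningless.
    """
    if check_alignment and traj.n_frames > 1:
        if not traj.metadata.get("aligned_chains") and "pathways" not in traj.metadata:
            raise ValueError(
                "trajectory is not subunit-aligned; run "
                "flipscan.io.align_subunit first (or pass check_alignment=False)"
            )
    idx = traj.select(role=role, name=name)
    if center is None:
        gc = traj.metadata.get("groove_center", (0.0, 0.0))
        center = (gc[0], gc[1], 0.0)
    half = np.asarray(extents) / 2.0
    origin = np.asarray(center, dtype=float) - half
    nbins = np.round(np.asarray(extents) / spacing).astype(int)
    pos = traj.coords[:, idx, :].reshape(-1, 3)
    counts, _ = np.histogramdd(
        pos,
        bins=nbins,
        range=[(origin[d], origin[d] + nbins[d] * spacing) for d in range(3)],
    )
    return DensityGrid(
        origin=origin, spacing=spacing, counts=counts, n_frames=traj.n_frames
    )


def average_grids(grids: list[DensityGrid]) -> DensityGrid:
    """Average per-subunit grids mapped into a common groove-local frame."""
    if not grids:
        raise ValueError("no grids to average")
    base = grids[0]
    for g in grids[1:]:
        if g.shape != base.shape or g.spacing != base.spacing:
            raise ValueError("grids must share shape and spacing to average")
    counts = np.mean([g.counts for g in grids], axis=0)
    return DensityGrid(
        origin=base.origin.copy(),
        spacing=base.spacing,
        counts=counts,
        n_frames=base.n_frames,
        n_chains=len(grids),
    )


def extract_pathway(
    grid: DensityGrid,
    z_range: tuple[float, float] | None = None,
    tube_radius: float = 15.0,
    start_xy: tuple[float, float] | None = None,
    max_empty_fraction: float = 0.2,
) -> Pathway:
    """Trace the maximum-density route through the grid, slab by slab.

    For every z slab the candidate cell is the density argmax within
    ``tube_radius`` of the previous node (first slab: of ``start_xy``,
    default the grid's lateral center); the node is the density-weighted
    centroid of the candidate's 3x3 in-plane neighborhood.  Empty slabs
    are interpolated between their flanking slabs, but more than
    ``max_empty_fraction`` empty slabs is an error.
    """
    nx, ny, nz = grid.shape
    h = grid.spacing
    zc = grid.cell_centers_z()
    if z_range is not None:
        sel = (zc >= z_range[0]) & (zc <= z_range[1])
    else:
        sel = np.ones(nz, dtype=bool)
    ks = np.flatnonzero(sel)
    if len(ks) == 0:
        raise ValueError("z_range excludes every slab")

    xs = grid.origin[0] + (np.arange(nx) + 0.5) * h
    ys = grid.origin[1] + (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    if start_xy is None:
        start_xy = (xs.mean(), ys.mean())
    prev = np.asarray(start_xy, dtype=float)

    nodes: list[tuple[float, float, float] | None] = []
    n_empty = 0
    for k in ks:
        slab = grid.counts[:, :, k]
        within = (XX - prev[0]) ** 2 + (YY - prev[1]) ** 2 <= tube_radius**2
        cand = np.where(within, slab, 0.0)
        if cand.max() <= 0:
            n_empty += 1
            nodes.append(None)
            continue
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        i0, i1 = max(0, i - 1), min(nx, i + 2)
        j0, j1 = max(0, j - 1), min(ny, j + 2)
        w = slab[i0:i1, j0:j1]
        x = float(np.sum(XX[i0:i1, j0:j1] * w) / w.sum())
        y = float(np.sum(YY[i0:i1, j0:j1] * w) / w.sum())
        nodes.append((x, y, float(zc[k])))
        prev = np.array([x, y])

    if n_empty > max_empty_fraction * len(ks):
        raise ValueError(
            f"{n_empty}/{len(ks)} slabs have zero density inside the tube"
        )
    # linear interpolation through empty slabs
    filled = [(i, n) for i, n in enumerate(nodes) if n is not None]
    if len(filled) < 2:
        raise ValueError("too few non-empty slabs for a pathway")
    fi = np.array([i for i, _ in filled])
    fx = np.array([n[0] for _, n in filled])
    fy = np.array([n[1] for _, n in filled])
    out = []
    for i, n in enumerate(nodes):
        if n is not None:
            out.append(n)
        else:
            out.append(
                (float(np.interp(i, fi, fx)), float(np.interp(i, fi, fy)),
                 float(zc[ks[i]]))
            )
    return Pathway(np.asarray(out), source="density")


def export_grid(grid: DensityGrid, path: str | os.PathLike) -> None:
    """Write the grid as an OpenDX scalar field (VMD/PyMOL readable)."""
    from gridData import Grid

    edges = [
        grid.origin[d] + np.arange(grid.shape[d] + 1) * grid.spacing
        for d in range(3)
    ]
    Grid(grid.counts, edges=edges).export(str(path), file_format="dx")


def load_grid(path: str | os.PathLike) -> DensityGrid:
    from gridData import Grid

    g = Grid(str(path))
    spacing = float(g.delta[0])
    origin = np.asarray(g.origin, dtype=float) - spacing / 2.0
    return DensityGrid(
        origin=origin, spacing=spacing, counts=np.asarray(g.grid),
        n_frames=0,
    )
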