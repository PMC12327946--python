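"""Membrane-spanning pathway polylines.

A :class:`Pathway` is an ordered set of 3D nodes with strictly increasing
z, running from below the lower leaflet surface to above the upper one.
It is produced either from a maximum-density search
(:func:`flipscan.density.extract_pathway`) or constructed synthetically,
and is consumed by event classification, permeation counting and the
free-energy/kinetics analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class Pathway:
    nodes: np.ndarray  # (M, 3) in angstrom, z strictly increasing
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must have shape (M, 3)")
        if len(self.nodes) < 2:
            raise ValueError("pathway needs at least 2 nodes")
        if not np.all(np.diff(self.nodes[:, 2]) > 0):
            raise ValueError("pathway nodes must have strictly increasing z")

    @property
    def z_min(self) -> float:
        return float(self.nodes[0, 2])

    @property
    def z_max(self) -> float:
        return float(self.nodes[-1, 2])

    def xy_at_z(self, z) -> np.ndarray:
        """Lateral position of the pathway at height ``z`` (linear interp,
        clamped to the end nodes outside the spanned range)."""
        scalar = np.ndim(z) == 0
        z = np.atleast_1d(np.asarray(z, dtype=float))
        x = np.interp(z, self.nodes[:, 2], self.nodes[:, 0])
        y = np.interp(z, self.nodes[:, 2], self.nodes[:, 1])
        out = np.stack([x, y], axis=-1)
        return out[0] if scalar else out

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Distance from each 3D point to the nearest pathway node."""
        from scipy.spatial import cKDTree

        pts = np.atleast_2d(points)
        d, _ = cKDTree(self.nodes).query(pts)
        return d

    def lateral_distance(self, points: np.ndarray) -> np.ndarray:
        """In-plane distance from each point to the pathway at the point's z."""
        pts = np.atleast_2d(points)
        xy = self.xy_at_z(pts[:, 2])
        return np.linalg.norm(np.atleast_2d(xy) - pts[:, :2], axis=1)

    def to_dict(self) -> dict:
        return {"nodes": self.nodes.tolist(), "source": self.source}

    @classmethod
    def from_dict(cls, d: dict) -> "Pathway":
        return cls(nodes=np.asarray(d["nodes"]), source=d.get("source", "synthetic"))


def straight_pathway(
    x: float, y: float, z_min: float, z_max: float, spacing: float = 1.0,
    source: str = "synthetic",
) -> Pathway:
    """Vertical pathway at fixed (x, y)."""
    z = np.arange(z_min, z_max + spacing / 2, spacing)
    nodes = np.column_stack([np.full_like(z, x), np.full_like(z, y), z])
    return Pathway(nodes, source=source)


def polyline_pathway(points, spacing: float = 1.0, source: str = "synthetic") -> Pathway:
    """Resample a coarse 3D polyline (z increasing) onto a regular z grid."""
    pts = np.asarray(points, dtype=float)
    z = np.arange(pts[0, 2], pts[-1, 2] + spacing / 2, spacing)
    x = np.interp(z, pts[:, 2], pts[:, 0])
    y = np.interp(z, pts[:, 2], pts[:, 1])
    return Pathway(np.column_stack([x, y, z]), source=source)
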