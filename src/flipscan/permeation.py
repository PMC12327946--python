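"""Directed water/ion permeation counting and selectivity ratios.

Each particle is tracked through three zones — below the membrane span,
inside it, above it — and a directed permeation event is recorded when a
particle that entered the middle zone from one side leaves to the
opposite side, provided it was within the pathway tube when it crossed
the midplane.  Re-crossings count separately; particles that enter and
retreat (even past the midplane) count nothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import Trajectory
from .pathway import Pathway

TUBE_RADIUS = 8.0  # angstrom
Z_MARGIN = 5.0  # angstrom beyond the leaflet surfaces

_SPECIES_ROLE = {"water": "water", "Na": "ion_cation", "Cl": "ion_anion"}


@dataclasses.dataclass
class PermeationCounts:
    species: str
    up_count: int
    down_count: int
    tube_radius: float
    z_bounds: tuple[float, float]
    rate_per_us: float = 0.0

    @property
    def total(self) -> int:
        return self.up_count + self.down_count

    @property
    def net(self) -> int:
        return self.up_count - self.down_count


@dataclasses.dataclass
class SelectivityRatio:
    p_na_over_cl: float  # inf marker when n_cl == 0 < n_na; nan when both 0
    n_na: int
    n_cl: int


def count_permeation(
    traj: Trajectory,
    species: str,
    pathway: Pathway,
    tube_radius: float = TUBE_RADIUS,
    z_bounds: tuple[float, float] | None = None,
    z_margin: float = Z_MARGIN,
) -> PermeationCounts:
    """Count directed membrane transits of one species through the tube.

    ``z_bounds`` are the leaflet surface heights; they default to
    +/- bulk_thickness/2 from the trajectory metadata and are then padded
    by ``z_margin`` to place the below/above zone boundaries safely
    outside the membrane.
    """
    if pathway is None:
        raise ValueError("a pathway is required for permeation counting")
    if z_bounds is None:
        b = traj.metadata.get("bulk_thickness", 30.0)
        z_bounds = (-b / 2.0, b / 2.0)
    z_lo = z_bounds[0] - z_margin
    z_hi = z_bounds[1] + z_margin
    z_mid = 0.5 * (z_lo + z_hi)

    idx = traj.select(role=_SPECIES_ROLE[species])
    up = down = 0
    for i in idx:
        pos = traj.coords[:, i, :]
        z = pos[:, 2]
        zone = np.where(z < z_lo, -1, np.where(z > z_hi, 1, 0))
        crossings = np.flatnonzero(np.diff(np.sign(z - z_mid)) != 0)
        entered_from = 0  # which side the particle came into the tube from
        prev = zone[0]
        for f in np.flatnonzero(np.diff(zone) != 0) + 1:
            zn = zone[f]
            if prev != 0 and zn == 0:
                entered_from = prev
            elif zn != 0:
                if entered_from == -zn and entered_from != 0:
                    # completed a transit; check the tube at the midplane crossing
                    before = crossings[crossings < f]
                    f_cross = int(before[-1]) if len(before) else f
                    lat = pathway.lateral_distance(pos[f_cross : f_cross + 1])[0]
                    if lat <= tube_radius:
                        if zn > 0:
                            up += 1
                        else:
                            down += 1
                entered_from = 0
            prev = zn
    duration_us = traj.duration / 1000.0
    return PermeationCounts(
        species=species, up_count=up, down_count=down,
        tube_radius=tube_radius, z_bounds=(z_lo, z_hi),
        rate_per_us=(up + down) / duration_us if duration_us > 0 else 0.0,
    )


def selectivity(
    counts_na: PermeationCounts, counts_cl: PermeationCounts
) -> SelectivityRatio:
    """Cation-to-anion permeability ratio from total counts (P_Na/P_Cl)."""
    n_na, n_cl = counts_na.total, counts_cl.total
    if n_cl > 0:
        ratio = n_na / n_cl
    elif n_na > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    return SelectivityRatio(p_na_over_cl=ratio, n_na=n_na, n_cl=n_cl)
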