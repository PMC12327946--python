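"""Internal trajectory model.

All coordinates are stored in angstrom and all times in nanoseconds,
matching the units in which membrane-analysis thresholds (angles,
distances, dwell times) are conventionally quoted for coarse-grained
bilayer simulations.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

ROLES = (
    "lipid_head",
    "lipid_phosphate",
    "lipid_glycerol",
    "lipid_tail_terminal",
    "protein",
    "water",
    "ion_cation",
    "ion_anion",
    "other",
)

#: Default bead-name -> role table for Martini 3 phosphatidylcholine lipids
#: (DOPC/POPC naming), protein backbone/side-chain beads, water, and NaCl.
#: Keys may be plain bead names or "RESNAME:BEAD" pairs; the qualified form
#: takes precedence.  Users extend or override this via the ``role_map``
#: argument of :func:`flipscan.io.load_trajectory`.
DEFAULT_ROLE_MAP: dict[str, str] = {
    "NC3": "lipid_head",
    "PO4": "lipid_phosphate",
    "GL1": "lipid_glycerol",
    "GL2": "lipid_glycerol",
    "C4A": "lipid_tail_terminal",
    "C4B": "lipid_tail_terminal",
    # mid-tail beads of DOPC/POPC: tracked but not used by any analysis
    "C1A": "other",
    "C2A": "other",
    "C3A": "other",
    "D2A": "other",
    "C1B": "other",
    "C2B": "other",
    "C3B": "other",
    "D2B": "other",
    "BB": "protein",
    "SC1": "protein",
    "SC2": "protein",
    "SC3": "protein",
    "SC4": "protein",
    "SC5": "protein",
    "W": "water",
    "NA": "ion_cation",
    "NA+": "ion_cation",
    "CL": "ion_anion",
    "CL-": "ion_anion",
}

LIPID_ROLES = frozenset(
    {"lipid_head", "lipid_phosphate", "lipid_glycerol", "lipid_tail_terminal"}
)


class UnknownBeadError(ValueError):
    """Raised when bead names cannot be mapped to a role."""


@dataclasses.dataclass(frozen=True)
class Bead:
    """A single coarse-grained bead with its topology labels."""

    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    role: str


def resolve_roles(
    names: Sequence[str],
    resnames: Sequence[str],
    role_map: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Map bead names to roles via the (user-extensible) role table.

    Lookup order: ``"RESNAME:BEAD"`` then bare ``"BEAD"``.  Any bead that
    resolves to nothing is a hard error listing every offender, so that a
    mistyped topology fails loudly instead of silently dropping beads.
    """
    table = dict(DEFAULT_ROLE_MAP)
    if role_map:
        table.update(role_map)
    roles = np.empty(len(names), dtype=object)
    unknown: set[str] = set()
    for i, (nm, rn) in enumerate(zip(names, resnames)):
        role = table.get(f"{rn}:{nm}") or table.get(nm)
        if role is None:
            unknown.add(nm)
        elif role not in ROLES:
            raise ValueError(f"role_map maps {nm!r} to unknown role {role!r}")
        else:
            roles[i] = role
    if unknown:
        raise UnknownBeadError(
            "no role for bead name(s): " + ", ".join(sorted(unknown))
        )
    return roles.astype("U20")


@dataclasses.dataclass
class Trajectory:
    """Time-ordered bead coordinates plus topology labels.

    ``coords`` has shape ``(n_frames, n_beads, 3)`` in angstrom; ``box``
    has shape ``(n_frames, 3)`` (orthorhombic box lengths).  ``dt`` is the
    frame spacing and ``t0`` the absolute time of the first retained frame,
    both in nanoseconds.
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    roles: np.ndarray
    coords: np.ndarray
    dt: float
    box: np.ndarray
    t0: float = 0.0
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        n = self.coords.shape[1]
        for arr_name in ("names", "resids", "resnames", "chains", "roles"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != bead count {n}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be > 0")

    # -- basic shape ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Absolute frame times in ns."""
        return self.t0 + np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        """Retained time span in ns (frame count times spacing)."""
        return self.n_frames * self.dt

    @property
    def beads(self) -> list[Bead]:
        return [
            Bead(str(n), int(ri), str(rn), str(c), str(ro))
            for n, ri, rn, c, ro in zip(
                self.names, self.resids, self.resnames, self.chains, self.roles
            )
        ]

    # -- selections -----------------------------------------------------
    def select(
        self,
        name: str | Iterable[str] | None = None,
        role: str | Iterable[str] | None = None,
        chain: str | Iterable[str] | None = None,
        resid: int | tuple[int, int] | Iterable[int] | None = None,
        resname: str | Iterable[str] | None = None,
    ) -> np.ndarray:
        """Return bead indices matching all given criteria.

        ``resid`` may be a single index, an inclusive ``(lo, hi)`` range,
        or an explicit list of residue indices.
        """
        mask = np.ones(self.n_beads, dtype=bool)

        def _match(values: np.ndarray, sel) -> np.ndarray:
            if isinstance(sel, str):
                sel = [sel]
            return np.isin(values, np.asarray(list(sel)))

        if name is not None:
            mask &= _match(self.names, name)
        if role is not None:
            mask &= _match(self.roles, role)
        if chain is not None:
            mask &= _match(self.chains, chain)
        if resname is not None:
            mask &= _match(self.resnames, resname)
        if resid is not None:
            if isinstance(resid, tuple) and len(resid) == 2:
                lo, hi = resid
                mask &= (self.resids >= lo) & (self.resids <= hi)
            elif np.isscalar(resid):
                mask &= self.resids == resid
            else:
                mask &= np.isin(self.resids, np.asarray(list(resid)))
        return np.flatnonzero(mask)

    def lipid_resids(self) -> np.ndarray:
        """Sorted residue indices of lipids (residues owning a head bead)."""
        return np.unique(self.resids[self.roles == "lipid_head"])

    # -- copies ---------------------------------------------------------
    def copy(self) -> "Trajectory":
        return Trajectory(
            names=self.names.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            chains=self.chains.copy(),
            roles=self.roles.copy(),
            coords=self.coords.copy(),
            dt=self.dt,
            box=self.box.copy(),
            t0=self.t0,
            metadata=dict(self.metadata),
        )

    def slice_frames(self, start: int, stop: int | None = None) -> "Trajectory":
        out = self.copy()
        out.coords = self.coords[start:stop].copy()
        out.box = self.box[start:stop].copy()
        out.t0 = self.t0 + start * self.dt
        return out


@dataclasses.dataclass(frozen=True)
class SubunitSpec:
    """Which residues of which chain define a subunit's alignment frame."""

    chain_id: str
    reference_selection: tuple[tuple[int, int], ...]
    bead_names: tuple[str, ...] = ("BB",)

    def resolve(self, traj: Trajectory) -> np.ndarray:
        idx: list[np.ndarray] = []
        for lo, hi in self.reference_selection:
            idx.append(
                traj.select(
                    chain=self.chain_id, resid=(lo, hi), name=list(self.bead_names)
                )
            )
        out = np.unique(np.concatenate(idx)) if idx else np.array([], dtype=int)
        if len(out) < 3:
            raise ValueError(
                f"subunit selection for chain {self.chain_id!r} resolves to "
                f"{len(out)} beads; need at least 3"
            )
        return out
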