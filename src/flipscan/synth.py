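"""Seeded synthetic coarse-grained bilayer trajectories with ground truth.

The generator emulates the statistical structure that the analyses in this
package assume: a two-leaflet phosphatidylcholine bilayer (six beads per
lipid: NC3, PO4, GL1/GL2, C4A/C4B) around a rigid two-column protein
scaffold ("TM4"/"TM6"), with

* Poisson-scheduled or explicitly scheduled leaflet transitions whose
  headgroups follow a configurable pathway polyline,
* partial excursions that enter the orientation-angle band but return,
* analytic leaflet deformation fields (Gaussian pinch or sinusoid) with a
  closed-form minimal thickness,
* isotropic positional jitter and lateral lipid diffusion,
* tracer particles (water beads, Na+, Cl-) that cross the membrane at
  planted times plus non-crossing decoys, and
* planted protein-lipid contact intervals.

Lipids and tracers follow kinematic scripts only; there is no force field
and no energetics.  Every draw goes through one ``numpy`` generator seeded
from the spec, so identical specs give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .model import Trajectory, resolve_roles
from .pathway import Pathway, straight_pathway

# -- lipid geometry ------------------------------------------------------
# Bead positions along the head->tail director, in angstrom.  The 15 A
# head-to-tail span together with a 30 degree resting tilt puts resting
# orientation angles near 150 (upper leaflet) and 30 degrees (lower),
# matching what is observed for CG phosphatidylcholine lipids rather than
# an idealized 180/0.
LIPID_BEAD_NAMES = ("NC3", "PO4", "GL1", "GL2", "C4A", "C4B")
_S_ALONG = np.array([0.0, 3.0, 6.75, 6.75, 15.0, 15.0])
_SPLAY = np.array([0.0, 0.0, 0.75, -0.75, 1.5, -1.5])
_S_GLMID = 6.75  # glycerol midpoint anchors the leaflet surface
_TILT_DEG = 30.0
_HEAD_LIFT = _S_GLMID * np.cos(np.radians(_TILT_DEG))  # NC3 height above GL mid

THETA_UPPER = 180.0 - _TILT_DEG  # resting angle in the upper leaflet
THETA_LOWER = _TILT_DEG


def _director(theta_deg, phi):
    """Unit head->tail vector(s) for polar angle theta (vs +z) and azimuth phi."""
    th = np.radians(np.asarray(theta_deg, dtype=float))
    ph = np.radians(np.asarray(phi, dtype=float))
    return np.stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1
    )


def _lipid_offsets(theta_deg: float, phi_deg: float) -> np.ndarray:
    """(6, 3) bead offsets from the NC3 bead for a rigid lipid pose."""
    u = _director(theta_deg, phi_deg)
    ph = np.radians(phi_deg)
    v = np.array([-np.sin(ph), np.cos(ph), 0.0])
    return _S_ALONG[:, None] * u[None, :] + _SPLAY[:, None] * v[None, :]


def _render_track(head: np.ndarray, theta: np.ndarray, phi: float) -> np.ndarray:
    """Render a (F, 6, 3) bead track from an NC3 trajectory and angle series."""
    u = _director(theta, np.full_like(theta, phi))
    ph = np.radians(phi)
    v = np.array([-np.sin(ph), np.cos(ph), 0.0])
    return (
        head[:, None, :]
        + _S_ALONG[None, :, None] * u[:, None, :]
        + _SPLAY[None, :, None] * v[None, None, :]
    )


def _smoothstep(p):
    p = np.clip(p, 0.0, 1.0)
    return p * p * (3.0 - 2.0 * p)


# -- specs ---------------------------------------------------------------

@dataclasses.dataclass
class DeformationSpec:
    """Analytic leaflet deformation.

    ``gaussian_pinch``: both leaflets are drawn toward the midplane by
    ``amplitude * exp(-r^2 / (2 width^2))`` around ``center``; the minimal
    leaflet-to-leaflet distance is then exactly
    ``bulk_thickness - 2 * amplitude``.
    ``sinusoid``: depth ``amplitude/2 * (1 + cos(2 pi (x - x0)/wavelength))``,
    maximal (= amplitude) at x = x0.
    """

    kind: str = "none"  # none | gaussian_pinch | sinusoid
    amplitude: float = 0.0
    width: float = 10.0
    center: tuple[float, float] = (0.0, 0.0)
    wavelength: float = 50.0

    def depth(self, xy: np.ndarray) -> np.ndarray:
        """Pinch depth (>= 0) at lateral position(s) xy, shape (..., 2)."""
        xy = np.asarray(xy, dtype=float)
        if self.kind == "none" or self.amplitude == 0.0:
            return np.zeros(xy.shape[:-1])
        if self.kind == "gaussian_pinch":
            r2 = (xy[..., 0] - self.center[0]) ** 2 + (xy[..., 1] - self.center[1]) ** 2
            return self.amplitude * np.exp(-r2 / (2.0 * self.width**2))
        if self.kind == "sinusoid":
            ph = 2.0 * np.pi * (xy[..., 0] - self.center[0]) / self.wavelength
            return 0.5 * self.amplitude * (1.0 + np.cos(ph))
        raise ValueError(f"unknown deformation kind {self.kind!r}")

    def analytic_min_thickness(self, bulk_thickness: float) -> float:
        if self.kind == "none" or self.amplitude == 0.0:
            return float(bulk_thickness)
        # both leaflets pinch symmetrically; the surfaces are closest where
        # the depth is maximal (= amplitude for both supported fields) and
        # the closest pair is the vertical one through that point
        return float(bulk_thickness - 2.0 * self.amplitude)


@dataclasses.dataclass
class BreathingSpec:
    """Oscillating TM4-TM6 separation (square or triangle wave)."""

    period: float = 1000.0  # ns
    duty: float = 0.5  # fraction of each period spent at open_sep
    closed_sep: float = 4.0  # angstrom
    open_sep: float = 8.0
    waveform: str = "square"  # square | triangle

    def separation(self, t: np.ndarray) -> np.ndarray:
        phase = np.mod(np.asarray(t, dtype=float), self.period) / self.period
        if self.waveform == "square":
            return np.where(phase < self.duty, self.open_sep, self.closed_sep)
        tri = 1.0 - np.abs(1.0 - 2.0 * phase)
        return self.closed_sep + (self.open_sep - self.closed_sep) * tri


@dataclasses.dataclass
class ScaffoldSpec:
    """Two rigid bead columns spanning the membrane, mimicking the TM4 and
    TM6 helices that line the scrambling groove."""

    tm4_range: tuple[int, int] = (327, 339)
    tm6_range: tuple[int, int] = (430, 452)
    separation: float = 8.0  # angstrom between the BB columns
    z_extent: tuple[float, float] = (-18.0, 18.0)
    chain_id: str = "A"
    dimer: bool = False
    dimer_offset: tuple[float, float] = (0.0, 40.0)

    def groove_center(self) -> tuple[float, float]:
        return (0.0, 0.0)


@dataclasses.dataclass
class ContactPlan:
    """Planted protein-lipid contact intervals for one residue.

    ``intervals`` are inclusive (start, stop) times in ns; during each
    interval a dedicated lipid parks its headgroup ~4 A from the residue's
    outermost bead, otherwise it parks ~19 A away.
    """

    resid: int
    chain_id: str = "A"
    intervals: tuple[tuple[float, float], ...] = ()
    head_bead: str = "NC3"


@dataclasses.dataclass
class TracerTransit:
    species: str  # water | Na | Cl
    t_cross: float  # ns, midpoint of the transit
    direction: str = "up"  # up | down
    duration: float = 20.0  # ns spent in transit


@dataclasses.dataclass
class SyntheticSpec:
    n_lipids_per_leaflet: int = 64
    box: tuple[float, float, float] = (100.0, 100.0, 100.0)
    bulk_thickness: float = 30.0
    duration: float = 1000.0  # ns
    dt: float = 1.0  # ns
    jitter_sigma: float = 1.0  # angstrom, isotropic per bead per frame
    lateral_diffusion: float = 1.0  # angstrom^2/ns lipid lateral walk
    seed: int = 0
    flip_rate: float = 0.0  # complete flips per microsecond (Poisson)
    partial_excursion_rate: float = 0.0  # per microsecond
    flip_schedule: tuple = ()  # explicit (t_start, pathway_label, complete)
    transit_time: float = 100.0  # ns for a planted flip
    pathway_spec: str = "groove_axis"  # groove_axis | dimer_cleft
    cleft_offset: tuple[float, float] = (20.0, 0.0)
    deformation: DeformationSpec = dataclasses.field(default_factory=DeformationSpec)
    scaffold: ScaffoldSpec | None = dataclasses.field(default_factory=ScaffoldSpec)
    breathing: BreathingSpec | None = None
    tracer_spec: tuple = ()  # TracerTransit entries
    n_decoy_tracers: int = 0
    n_groove_waters: int = 0
    contact_spec: tuple = ()  # ContactPlan entries

    def validate(self) -> None:
        if self.flip_rate < 0 or self.partial_excursion_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.transit_time <= 0:
            raise ValueError("transit_time must be > 0")
        if self.deformation.amplitude >= self.bulk_thickness / 2:
            raise ValueError("deformation amplitude must be < bulk_thickness/2")
        area = self.box[0] * self.box[1]
        if area / max(self.n_lipids_per_leaflet, 1) < 40.0:
            raise ValueError(
                "lipid count incompatible with box area (less than 40 A^2 "
                "per lipid would overlap)"
            )


@dataclasses.dataclass
class PlantedEvent:
    lipid_id: int
    direction: str  # upper_to_lower | lower_to_upper
    t_complete: float  # scheduled completion time, ns
    pathway: str  # groove_axis | dimer_cleft | custom
    label: str  # in_groove | out_of_groove


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator planted, for validating the analyses."""

    events: list = dataclasses.field(default_factory=list)
    partials: list = dataclasses.field(default_factory=list)
    analytic_min_thickness: float = 30.0
    planted_crossings: dict = dataclasses.field(default_factory=dict)
    planted_contact_intervals: dict = dataclasses.field(default_factory=dict)
    open_duty: float | None = None

    def to_dict(self) -> dict:
        return {
            "events": [dataclasses.asdict(e) for e in self.events],
            "partials": list(self.partials),
            "analytic_min_thickness": self.analytic_min_thickness,
            "planted_crossings": self.planted_crossings,
            "planted_contact_intervals": self.planted_contact_intervals,
            "open_duty": self.open_duty,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls(
            analytic_min_thickness=d.get("analytic_min_thickness", 30.0),
            planted_crossings=d.get("planted_crossings", {}),
            planted_contact_intervals={
                k: [tuple(iv) for iv in v]
                for k, v in d.get("planted_contact_intervals", {}).items()
            },
            open_duty=d.get("open_duty"),
        )
        gt.events = [PlantedEvent(**e) for e in d.get("events", [])]
        gt.partials = [tuple(p) for p in d.get("partials", [])]
        return gt

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- scheduling ----------------------------------------------------------

def schedule_poisson_events(
    rate_per_us: float, duration_ns: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times (ns) of a homogeneous Poisson process.

    Inter-event gaps are exponential with mean ``1000 / rate_per_us`` ns.
    """
    if rate_per_us <= 0:
        return np.empty(0)
    mean_gap = 1000.0 / rate_per_us
    # draw enough gaps to overshoot the duration with near-certainty
    n_guess = max(16, int(duration_ns / mean_gap * 2 + 10 * np.sqrt(duration_ns / mean_gap)))
    times = np.cumsum(rng.exponential(mean_gap, size=n_guess))
    while times[-1] < duration_ns:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.exponential(mean_gap, size=n_guess))]
        )
    return times[times < duration_ns]


# -- scaffold ------------------------------------------------------------

def _build_scaffold(spec: SyntheticSpec):
    """Static (or breathing) protein bead arrays.

    Each residue has a BB bead on its column axis and, for non-glycine
    residues, an SC1 bead 2 A radially outward from the groove.  Every
    fourth residue is glycine (backbone only), exercising the
    backbone-substitution rule of the contact analysis.
    """
    sc = spec.scaffold
    names, resids, resnames, chains = [], [], [], []
    base_pos = []
    column = []  # +1 for TM4 (at -sep/2), -1 for TM6 (at +sep/2) sign of x offset
    resname_cycle = ("ILE", "LEU", "GLY", "THR")
    for rng_lo_hi, xsign in ((sc.tm4_range, -1.0), (sc.tm6_range, +1.0)):
        lo, hi = rng_lo_hi
        n_res = hi - lo + 1
        zs = np.linspace(sc.z_extent[0], sc.z_extent[1], n_res)
        for k, resid in enumerate(range(lo, hi + 1)):
            rn = resname_cycle[k % len(resname_cycle)]
            x0 = xsign * sc.separation / 2.0
            names.append("BB")
            resids.append(resid)
            resnames.append(rn)
            chains.append(sc.chain_id)
            base_pos.append((x0, 0.0, zs[k]))
            column.append(xsign)
            if rn != "GLY":
                names.append("SC1")
                resids.append(resid)
                resnames.append(rn)
                chains.append(sc.chain_id)
                base_pos.append((x0 + xsign * 2.0, 0.0, zs[k]))
                column.append(xsign)
    base_pos = np.asarray(base_pos)
    column = np.asarray(column)

    chains = list(chains)
    if sc.dimer:
        dx, dy = sc.dimer_offset
        names = names + names
        resids = resids + resids
        resnames = resnames + resnames
        chains = chains + ["B"] * len(chains)
        mirrored = base_pos.copy()
        mirrored[:, 0] = -mirrored[:, 0] + dx
        mirrored[:, 1] += dy
        base_pos = np.vstack([base_pos, mirrored])
        column = np.concatenate([column, column])
    return names, resids, resnames, chains, base_pos, column


# -- main builder --------------------------------------------------------

def build_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a full synthetic trajectory plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    F = int(round(spec.duration / spec.dt))
    if F < 2:
        raise ValueError("duration must cover at least 2 frames")
    Lx, Ly, Lz = spec.box
    b = spec.bulk_thickness
    times = np.arange(F) * spec.dt

    # ---- protein scaffold
    if spec.scaffold is not None:
        (p_names, p_resids, p_resnames, p_chains, p_base, p_col) = _build_scaffold(spec)
    else:
        p_names, p_resids, p_resnames, p_chains = [], [], [], []
        p_base = np.empty((0, 3))
        p_col = np.empty(0)
    n_prot = len(p_names)

    # ---- lipid lattice (upper then lower leaflet)
    L = spec.n_lipids_per_leaflet
    nx = max(1, int(round(np.sqrt(L * Lx / Ly))))
    ny = int(np.ceil(L / nx))
    sx, sy = Lx / nx, Ly / ny
    sites = []
    for j in range(ny):
        for i in range(nx):
            sites.append(((i + 0.5) * sx - Lx / 2, (j + 0.5) * sy - Ly / 2))
    sites = np.asarray(sites[:L])

    lipid_sites = np.vstack([sites, sites])  # upper block then lower block
    leaflet_sign = np.concatenate([np.ones(L), -np.ones(L)])

    # dedicated contact lipids (parked far away; scripted later)
    n_contact = len(spec.contact_spec)

    n_lip = 2 * L + n_contact
    first_lipid_resid = 1001
    lipid_resids = np.arange(first_lipid_resid, first_lipid_resid + n_lip)

    # ---- tracers
    tracer_entries = [
        t if isinstance(t, TracerTransit) else TracerTransit(*t)
        for t in spec.tracer_spec
    ]
    n_tracer = len(tracer_entries) + spec.n_decoy_tracers + spec.n_groove_waters

    # ---- assemble topology arrays
    names = list(p_names)
    resids = list(p_resids)
    resnames = list(p_resnames)
    chains = list(p_chains)
    for r in lipid_resids:
        names.extend(LIPID_BEAD_NAMES)
        resids.extend([int(r)] * 6)
        resnames.extend(["DOPC"] * 6)
        chains.extend(["M"] * 6)
    _SPECIES_BEAD = {"water": ("W", "W"), "Na": ("NA", "NA"), "Cl": ("CL", "CL")}
    tracer_species: list[str] = [t.species for t in tracer_entries]
    for _ in range(spec.n_decoy_tracers):
        tracer_species.append("water")
    for _ in range(spec.n_groove_waters):
        tracer_species.append("water")
    tr_resid0 = first_lipid_resid + n_lip + 100
    for k, sp_name in enumerate(tracer_species):
        nm, rn = _SPECIES_BEAD[sp_name]
        names.append(nm)
        resids.append(tr_resid0 + k)
        resnames.append(rn)
        chains.append("X")
    names = np.asarray(names, dtype="U8")
    resids = np.asarray(resids, dtype=int)
    resnames = np.asarray(resnames, dtype="U8")
    chains = np.asarray(chains, dtype="U4")
    roles = resolve_roles(names, resnames)

    N = n_prot + 6 * n_lip + n_tracer
    coords = np.zeros((F, N, 3), dtype=np.float64)

    # ---- protein track (rigid, optionally breathing)
    duty = None
    if n_prot:
        coords[:, :n_prot, :] = p_base[None, :, :]
        if spec.breathing is not None:
            sep_t = spec.breathing.separation(times)  # (F,)
            base_sep = spec.scaffold.separation
            # shift each column so BB-BB distance follows sep_t
            shift = (sep_t - base_sep) / 2.0  # (F,)
            coords[:, :n_prot, 0] += p_col[None, :] * shift[:, None]
            duty = float(np.mean(sep_t == spec.breathing.open_sep)) if (
                spec.breathing.waveform == "square"
            ) else spec.breathing.duty

    # ---- lipid base render (resting poses, lateral walks, deformation)
    deform = spec.deformation
    sig_step = np.sqrt(2.0 * spec.lateral_diffusion * spec.dt)
    phi = rng.uniform(0.0, 360.0, size=n_lip)

    # anchors for the 2L lattice lipids; contact lipids handled separately
    steps = rng.normal(0.0, sig_step, size=(F - 1, 2 * L, 2))
    anchors = np.empty((F, 2 * L, 2))
    anchors[0] = lipid_sites
    np.cumsum(steps, axis=0, out=anchors[1:])
    anchors[1:] += lipid_sites[None, :, :]
    # wrap into the box (periodic)
    anchors[..., 0] = (anchors[..., 0] + Lx / 2) % Lx - Lx / 2
    anchors[..., 1] = (anchors[..., 1] + Ly / 2) % Ly - Ly / 2

    depth = deform.depth(anchors)  # (F, 2L)
    gl_z = leaflet_sign[None, :] * (b / 2.0 - depth)  # (F, 2L)

    for li in range(2 * L):
        s = leaflet_sign[li]
        theta = THETA_UPPER if s > 0 else THETA_LOWER
        offs = _lipid_offsets(theta, phi[li])  # (6, 3)
        glmid_to_nc3 = -_S_GLMID * _director(theta, phi[li])
        head = np.empty((F, 3))
        head[:, 0] = anchors[:, li, 0] + glmid_to_nc3[0]
        head[:, 1] = anchors[:, li, 1] + glmid_to_nc3[1]
        head[:, 2] = gl_z[:, li] + glmid_to_nc3[2]
        a0 = n_prot + 6 * li
        coords[:, a0 : a0 + 6, :] = head[:, None, :] + offs[None, :, :]

    # contact lipids: resting in the upper leaflet far corner until scripted
    for k in range(n_contact):
        li = 2 * L + k
        offs = _lipid_offsets(THETA_UPPER, phi[li])
        park = np.array([-Lx / 2 + 8.0 + 10.0 * k, -Ly / 2 + 8.0])
        head = np.empty((F, 3))
        head[:, :2] = park[None, :]
        head[:, 2] = b / 2.0 + _HEAD_LIFT
        a0 = n_prot + 6 * li
        coords[:, a0 : a0 + 6, :] = head[:, None, :] + offs[None, :, :]

    # ---- jitter on lipids (protein is rigid, tracers scripted below)
    if spec.jitter_sigma > 0:
        coords[:, n_prot : n_prot + 6 * n_lip, :] += rng.normal(
            0.0, spec.jitter_sigma, size=(F, 6 * n_lip, 3)
        )

    box = np.tile(np.asarray([Lx, Ly, Lz], dtype=float), (F, 1))
    traj = Trajectory(
        names=names, resids=resids, resnames=resnames, chains=chains,
        roles=roles, coords=coords, dt=spec.dt, box=box, t0=0.0,
    )
    groove_xy = spec.scaffold.groove_center() if spec.scaffold else (0.0, 0.0)
    z_lo, z_hi = -b / 2.0 - 10.0, b / 2.0 + 10.0
    pathways = {
        "groove_axis": straight_pathway(groove_xy[0], groove_xy[1], z_lo, z_hi),
        "dimer_cleft": straight_pathway(
            groove_xy[0] + spec.cleft_offset[0],
            groove_xy[1] + spec.cleft_offset[1],
            z_lo, z_hi,
        ),
    }
    traj.metadata.update(
        bulk_thickness=b,
        deformation=deform,
        lateral_diffusion=spec.lateral_diffusion,
        jitter_sigma=spec.jitter_sigma,
        groove_center=groove_xy,
        pathways=pathways,
        n_protein_beads=n_prot,
    )

    truth = GroundTruth(
        analytic_min_thickness=deform.analytic_min_thickness(b),
        open_duty=duty,
    )

    # ---- flips and partial excursions
    lattice_ids = list(lipid_resids[: 2 * L])
    current_leaflet = {
        int(r): (+1 if i < L else -1) for i, r in enumerate(lattice_ids)
    }
    busy_until = {int(r): -1.0 for r in lattice_ids}

    planned: list[tuple[float, str, bool]] = []
    for entry in spec.flip_schedule:
        t_start, pw_label, complete = entry
        planned.append((float(t_start), str(pw_label), bool(complete)))
    if spec.flip_rate > 0:
        for t in schedule_poisson_events(spec.flip_rate, spec.duration, rng):
            planned.append((float(t), spec.pathway_spec, True))
    if spec.partial_excursion_rate > 0:
        for t in schedule_poisson_events(
            spec.partial_excursion_rate, spec.duration, rng
        ):
            planned.append((float(t), spec.pathway_spec, False))
    planned.sort(key=lambda e: e[0])

    for t_start, pw_label, complete in planned:
        if t_start + spec.transit_time > spec.duration:
            continue  # would not finish inside the trajectory
        candidates = [
            r for r in lattice_ids if busy_until[r] < t_start
        ]
        if not candidates:
            continue
        lid = int(candidates[rng.integers(len(candidates))])
        busy_until[lid] = t_start + spec.transit_time
        plant_flip(
            traj, lid, t_start, pathways[pw_label], spec.transit_time,
            complete=complete, ground_truth=truth, rng=rng,
            pathway_label=pw_label,
        )
        if complete:
            current_leaflet[lid] = -current_leaflet[lid]

    # ---- tracers
    if tracer_entries or spec.n_decoy_tracers or spec.n_groove_waters:
        _script_tracers(traj, spec, tracer_entries, pathways, truth, rng,
                        n_prot + 6 * n_lip)

    # ---- planted contacts
    for k, plan in enumerate(spec.contact_spec):
        _script_contact(traj, spec, plan, int(lipid_resids[2 * L + k]), truth, rng)

    return traj, truth


# -- flips ---------------------------------------------------------------

def plant_flip(
    traj: Trajectory,
    lipid_id: int,
    t_start: float,
    pathway: Pathway,
    transit_time: float,
    complete: bool = True,
    ground_truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    pathway_label: str | None = None,
) -> Trajectory:
    """Script one leaflet transition (or partial excursion) onto a lipid.

    The headgroup slides along the pathway polyline with the tails
    trailing, so the orientation angle sweeps from its resting value
    through 90 degrees to the destination resting angle (complete) or
    turns back after reaching ~55 degrees from the pole (partial).  After a
    complete flip the lipid resumes a resting pose, and a fresh lateral
    walk, in the destination leaflet.  Mutates ``traj`` in place and
    returns it.
    """
    if rng is None:
        rng = np.random.default_rng((hash((int(lipid_id), round(t_start * 8))) & 0x7FFFFFFF))
    md = traj.metadata
    b = md.get("bulk_thickness")
    dt = traj.dt
    F = traj.n_frames
    f0 = int(round((t_start - traj.t0) / dt))
    nT = max(2, int(round(transit_time / dt)))
    f1 = f0 + nT
    if f0 < 0 or f1 > F:
        raise ValueError("flip window outside trajectory")

    idx = {}
    for nm in LIPID_BEAD_NAMES:
        sel = traj.select(resid=int(lipid_id), name=nm)
        if len(sel) != 1:
            raise ValueError(f"lipid {lipid_id} lacks a unique {nm} bead")
        idx[nm] = int(sel[0])
    order = np.array([idx[nm] for nm in LIPID_BEAD_NAMES])

    windows = md.setdefault("planted_windows", {}).setdefault(int(lipid_id), [])
    for (w0, w1) in windows:
        if t_start < w1 and t_start + transit_time > w0:
            raise ValueError(
                f"overlapping flips planted on lipid {lipid_id} "
                f"({t_start}-{t_start + transit_time} vs {w0}-{w1})"
            )
    windows.append((t_start, t_start + transit_time))

    gl_z0 = 0.5 * (traj.coords[f0, idx["GL1"], 2] + traj.coords[f0, idx["GL2"], 2])
    s = 1.0 if gl_z0 > 0 else -1.0
    if b is None:
        glz = traj.coords[f0, traj.roles == "lipid_glycerol", 2]
        b = 2.0 * float(np.mean(np.abs(glz)))
    deform = md.get("deformation", DeformationSpec())
    jitter = md.get("jitter_sigma", 0.0)
    d_lat = md.get("lateral_diffusion", 0.0)

    theta_start = THETA_UPPER if s > 0 else THETA_LOWER
    theta_end = THETA_LOWER if s > 0 else THETA_UPPER
    phi = float(rng.uniform(0.0, 360.0))

    start_xy = traj.coords[f0, idx["NC3"], :2].astype(float)
    land_xy = np.asarray(pathway.xy_at_z(-s * b / 4.0)) + rng.normal(0, 2.0, 2)
    z_head_start = s * ((b / 2.0 - float(deform.depth(start_xy))) + _HEAD_LIFT)
    z_head_end = -s * ((b / 2.0 - float(deform.depth(land_xy))) + _HEAD_LIFT)

    pg = np.arange(nT) / (nT - 1)
    if complete:
        p = _smoothstep(pg)
        theta = theta_start + (theta_end - theta_start) * p
        z_head = z_head_start + (z_head_end - z_head_start) * p
        path_xy = np.atleast_2d(pathway.xy_at_z(z_head))
        w_in = np.clip(pg / 0.25, 0.0, 1.0)
        w_out = np.clip((pg - 0.75) / 0.25, 0.0, 1.0)
        xy = (1 - w_in)[:, None] * start_xy[None, :] + w_in[:, None] * path_xy
        xy = (1 - w_out)[:, None] * xy + w_out[:, None] * land_xy[None, :]
    else:
        tri = 1.0 - np.abs(1.0 - 2.0 * pg)
        # turn back after reaching ~55 degrees from the destination pole
        theta_turn = 55.0 if s > 0 else 125.0
        theta = theta_start + (theta_turn - theta_start) * tri
        z_turn = s * 3.0
        z_head = z_head_start + (z_turn - z_head_start) * tri
        path_xy = np.atleast_2d(pathway.xy_at_z(z_head))
        w = np.clip(tri / 0.5, 0.0, 1.0) * 0.8
        xy = (1 - w)[:, None] * start_xy[None, :] + w[:, None] * path_xy

    head = np.column_stack([xy, z_head])
    track = _render_track(head, theta, phi)
    if jitter > 0:
        track = track + rng.normal(0.0, jitter, size=track.shape)
    traj.coords[f0:f1, order, :] = track

    if complete and f1 < F:
        # resting pose in the destination leaflet, new lateral walk
        n_rest = F - f1
        sig_step = np.sqrt(2.0 * d_lat * dt)
        walk = np.zeros((n_rest, 2))
        if sig_step > 0 and n_rest > 1:
            walk[1:] = np.cumsum(rng.normal(0, sig_step, size=(n_rest - 1, 2)), axis=0)
        anchor = land_xy[None, :] + walk
        depth = deform.depth(anchor)
        s2 = -s
        glmid_to_nc3 = -_S_GLMID * _director(theta_end, phi)
        head_r = np.empty((n_rest, 3))
        head_r[:, :2] = anchor + glmid_to_nc3[None, :2]
        head_r[:, 2] = s2 * (b / 2.0 - depth) + glmid_to_nc3[2]
        offs = _lipid_offsets(theta_end, phi)
        rest = head_r[:, None, :] + offs[None, :, :]
        if jitter > 0:
            rest = rest + rng.normal(0.0, jitter, size=rest.shape)
        traj.coords[f1:, order, :] = rest

    if ground_truth is not None:
        label_pw = pathway_label or "custom"
        if complete:
            groove = traj.metadata.get("pathways", {}).get("groove_axis")
            if groove is not None:
                mid = np.array([*pathway.xy_at_z(0.0), 0.0])
                in_groove = float(groove.distance_to(mid[None, :])[0]) <= 4.7
            else:
                in_groove = label_pw == "groove_axis"
            ground_truth.events.append(
                PlantedEvent(
                    lipid_id=int(lipid_id),
                    direction="upper_to_lower" if s > 0 else "lower_to_upper",
                    t_complete=float(t_start + transit_time),
                    pathway=label_pw,
                    label="in_groove" if in_groove else "out_of_groove",
                )
            )
        else:
            ground_truth.partials.append((int(lipid_id), float(t_start)))
    return traj


# -- deformation (post-hoc) ---------------------------------------------

def apply_deformation(
    traj: Trajectory, deformation: DeformationSpec
) -> tuple[Trajectory, float]:
    """Displace each lipid toward the midplane by the analytic field.

    Per frame, every lipid's beads are shifted in z by the pinch depth
    evaluated at its glycerol-midpoint lateral position, toward the
    midplane of its current leaflet (sign of the glycerol z).  Returns the
    modified trajectory and the closed-form minimal thickness.
    """
    b = traj.metadata.get("bulk_thickness", 30.0)
    lip_ids = traj.lipid_resids()
    gl1 = np.array([traj.select(resid=int(r), name="GL1")[0] for r in lip_ids])
    gl2 = np.array([traj.select(resid=int(r), name="GL2")[0] for r in lip_ids])
    bead_sets = np.stack(
        [np.sort(traj.select(resid=int(r))) for r in lip_ids]
    )  # (L, 6)
    glmid = 0.5 * (traj.coords[:, gl1, :] + traj.coords[:, gl2, :])  # (F, L, 3)
    depth = deformation.depth(glmid[:, :, :2])  # (F, L)
    sign = np.where(glmid[:, :, 2] > 0, 1.0, -1.0)
    dz = -sign * depth  # pull toward the midplane
    for j in range(bead_sets.shape[1]):
        traj.coords[:, bead_sets[:, j], 2] += dz
    traj.metadata["deformation"] = deformation
    return traj, deformation.analytic_min_thickness(b)


# -- tracers -------------------------------------------------------------

def _append_beads(traj: Trajectory, names, resids, resnames, chains) -> np.ndarray:
    """Grow the trajectory by new beads (coords zero); returns their indices."""
    k = len(names)
    new_names = np.concatenate([traj.names, np.asarray(names, dtype="U8")])
    new_resids = np.concatenate([traj.resids, np.asarray(resids, dtype=int)])
    new_resnames = np.concatenate([traj.resnames, np.asarray(resnames, dtype="U8")])
    new_chains = np.concatenate([traj.chains, np.asarray(chains, dtype="U4")])
    new_roles = resolve_roles(new_names, new_resnames)
    new_coords = np.concatenate(
        [traj.coords, np.zeros((traj.n_frames, k, 3))], axis=1
    )
    traj.names, traj.resids, traj.resnames = new_names, new_resids, new_resnames
    traj.chains, traj.roles, traj.coords = new_chains, new_roles, new_coords
    return np.arange(new_coords.shape[1] - k, new_coords.shape[1])


def _transit_z(times, t_cross, duration, direction, z_lo_park, z_hi_park):
    half = duration / 2.0
    a, bb = (z_lo_park, z_hi_park) if direction == "up" else (z_hi_park, z_lo_park)
    p = np.clip((times - (t_cross - half)) / duration, 0.0, 1.0)
    return a + (bb - a) * p


def _script_tracers(traj, spec, entries, pathways, truth, rng, first_idx):
    """Fill in the pre-allocated tracer bead coordinates."""
    F = traj.n_frames
    times = traj.times
    b = spec.bulk_thickness
    z_park = b / 2.0 + 12.0
    path = pathways[spec.pathway_spec if spec.pathway_spec in pathways else "groove_axis"]

    counts: dict[str, dict[str, int]] = {}
    k = first_idx
    for tr in entries:
        z = _transit_z(times, tr.t_cross, tr.duration, tr.direction, -z_park, z_park)
        xy = np.atleast_2d(path.xy_at_z(np.clip(z, path.z_min, path.z_max)))
        traj.coords[:, k, :2] = xy + rng.normal(0, 1.0, size=(F, 2))
        traj.coords[:, k, 2] = z + rng.normal(0, 0.5, size=F)
        c = counts.setdefault(tr.species, {"up": 0, "down": 0})
        c[tr.direction] += 1
        k += 1

    for _ in range(spec.n_decoy_tracers):
        side = 1.0 if rng.random() < 0.5 else -1.0
        t_mid = rng.uniform(0.15, 0.85) * spec.duration
        width = rng.uniform(15.0, 40.0)
        z_min = rng.uniform(-8.0, 8.0)  # may reach past the midplane, then retreat
        tri = np.clip(1.0 - np.abs(times - t_mid) / width, 0.0, 1.0)
        z = side * z_park - (side * z_park - z_min) * tri
        xy = np.atleast_2d(path.xy_at_z(np.clip(z, path.z_min, path.z_max)))
        traj.coords[:, k, :2] = xy + rng.normal(0, 1.5, size=(F, 2))
        traj.coords[:, k, 2] = z + rng.normal(0, 0.5, size=F)
        k += 1

    z_ref = b / 2.0 + 2.0
    for _ in range(spec.n_groove_waters):
        # reflected random walk along the groove axis, never past the faces
        z = np.empty(F)
        z[0] = rng.uniform(-z_ref, z_ref)
        steps = rng.normal(0, 2.0, size=F - 1)
        for f in range(1, F):
            zn = z[f - 1] + steps[f - 1]
            if zn > z_ref:
                zn = 2 * z_ref - zn
            elif zn < -z_ref:
                zn = -2 * z_ref - zn
            z[f] = zn
        xy = np.atleast_2d(path.xy_at_z(np.clip(z, path.z_min, path.z_max)))
        traj.coords[:, k, :2] = xy + rng.normal(0, 1.5, size=(F, 2))
        traj.coords[:, k, 2] = z
        k += 1

    truth.planted_crossings = counts


def plant_tracers(
    traj: Trajectory,
    tracer_spec: Sequence,
    pathway: Pathway,
    rng: np.random.Generator | None = None,
    n_decoys: int = 0,
    bulk_thickness: float | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Append tracer beads with planted transits (and decoys) to ``traj``.

    Decoys approach or cross the midplane but always retreat to their side
    of origin, so a correct permeation counter must ignore them.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    entries = [
        t if isinstance(t, TracerTransit) else TracerTransit(*t) for t in tracer_spec
    ]
    b = bulk_thickness or traj.metadata.get("bulk_thickness", 30.0)
    F = traj.n_frames
    times = traj.times
    z_park = b / 2.0 + 12.0
    duration = traj.duration

    _SPECIES_BEAD = {"water": ("W", "W"), "Na": ("NA", "NA"), "Cl": ("CL", "CL")}
    species = [e.species for e in entries] + ["water"] * n_decoys
    resid0 = int(traj.resids.max()) + 1
    idx = _append_beads(
        traj,
        [_SPECIES_BEAD[s][0] for s in species],
        [resid0 + i for i in range(len(species))],
        [_SPECIES_BEAD[s][1] for s in species],
        ["X"] * len(species),
    )

    counts: dict[str, dict[str, int]] = {}
    for k, tr in zip(idx, entries):
        z = _transit_z(times - traj.t0, tr.t_cross, tr.duration, tr.direction,
                       -z_park, z_park)
        xy = np.atleast_2d(pathway.xy_at_z(np.clip(z, pathway.z_min, pathway.z_max)))
        traj.coords[:, k, :2] = xy + rng.normal(0, 1.0, size=(F, 2))
        traj.coords[:, k, 2] = z + rng.normal(0, 0.5, size=F)
        c = counts.setdefault(tr.species, {"up": 0, "down": 0})
        c[tr.direction] += 1
    for k in idx[len(entries):]:
        side = 1.0 if rng.random() < 0.5 else -1.0
        t_mid = rng.uniform(0.15, 0.85) * duration
        width = rng.uniform(15.0, 40.0)
        z_min = rng.uniform(-8.0, 8.0)
        tri = np.clip(1.0 - np.abs(times - traj.t0 - t_mid) / width, 0.0, 1.0)
        z = side * z_park - (side * z_park - z_min) * tri
        xy = np.atleast_2d(pathway.xy_at_z(np.clip(z, pathway.z_min, pathway.z_max)))
        traj.coords[:, k, :2] = xy + rng.normal(0, 1.5, size=(F, 2))
        traj.coords[:, k, 2] = z + rng.normal(0, 0.5, size=F)

    truth = GroundTruth(planted_crossings=counts,
                        analytic_min_thickness=b)
    return traj, truth


# -- planted contacts ----------------------------------------------------

def _script_contact(traj, spec, plan: ContactPlan, lipid_resid: int, truth, rng):
    """Park a dedicated lipid near/far from a residue per the plan."""
    res_beads = traj.select(chain=plan.chain_id, resid=plan.resid)
    if len(res_beads) == 0:
        raise ValueError(f"contact plan residue {plan.resid} not in scaffold")
    # outermost bead: SC1 when present, else BB (glycine)
    sc = [i for i in res_beads if traj.names[i] == "SC1"]
    target_idx = sc[0] if sc else int(res_beads[0])
    target = traj.coords[0, target_idx]  # scaffold is rigid
    radial = np.array([np.sign(target[0]) if target[0] != 0 else 1.0, 0.0, 0.0])

    idx = {nm: int(traj.select(resid=lipid_resid, name=nm)[0])
           for nm in LIPID_BEAD_NAMES}
    order = np.array([idx[nm] for nm in LIPID_BEAD_NAMES])
    head_name = plan.head_bead
    s_head = _S_ALONG[LIPID_BEAD_NAMES.index(head_name)]
    theta = THETA_UPPER if target[2] >= 0 else THETA_LOWER
    phi = float(rng.uniform(0, 360))
    offs = _lipid_offsets(theta, phi)
    u = _director(theta, phi)

    near = target + 4.0 * radial - s_head * u  # puts head_bead 4 A from target
    far = target + 19.0 * radial - s_head * u

    F = traj.n_frames
    pos = np.tile(far, (F, 1))
    times = traj.times
    for (ta, tb) in plan.intervals:
        fa = int(round((ta - traj.t0) / traj.dt))
        fb = int(round((tb - traj.t0) / traj.dt))
        pos[fa : fb + 1] = near
    track = pos[:, None, :] + offs[None, :, :]
    if spec.jitter_sigma > 0:
        track = track + rng.normal(0, min(spec.jitter_sigma, 0.5),
                                   size=track.shape)
    traj.coords[:, order, :] = track
    key = f"{plan.chain_id}:{plan.resid}"
    truth.planted_contact_intervals[key] = [list(map(float, iv))
                                            for iv in plan.intervals]
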