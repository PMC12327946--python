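"""Energetics and kinetics of in-groove lipid transit.

The free-energy profile along the pathway is obtained by Boltzmann
inversion of the equilibrium headgroup density inside the groove tube,
G(s) = -kT ln(rho(s)/max rho), normalized so min G = 0.  Transit
kinetics are a per-event dwell time (contiguous time inside the tube
around the midplane crossing) and a diffusion coefficient fit from the
mean-squared displacement of the projected coordinate, MSD = 2 D tau,
over lag times of 1-10 ns.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import Trajectory
from .pathway import Pathway


@dataclasses.dataclass
class FreeEnergyProfile:
    s: np.ndarray  # bin centers along the pathway (z projection), angstrom
    G: np.ndarray  # kT units; NaN in empty bins
    counts: np.ndarray
    barrier_height: float  # max G - min G over the requested span
    empty_bins: np.ndarray  # flagged, never silently interpolated


@dataclasses.dataclass
class TransitKinetics:
    transit_dwell_list: list  # ns per completed event
    D_estimate: float | None  # angstrom^2/ns
    D_stderr: float | None


def profile_from_samples(
    s_values: np.ndarray,
    bin_width: float = 1.0,
    kT: float = 1.0,
    s_range: tuple[float, float] | None = None,
    span: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Boltzmann inversion of a 1D sample histogram.

    ``span`` restricts the barrier-height readout (e.g. to the region
    between the two leaflet surfaces) without affecting the profile.
    """
    s_values = np.asarray(s_values, dtype=float)
    if len(s_values) == 0:
        raise ValueError("no samples to invert")
    if s_range is None:
        s_range = (s_values.min(), s_values.max() + 1e-9)
    nbins = max(1, int(np.ceil((s_range[1] - s_range[0]) / bin_width)))
    counts, edges = np.histogram(s_values, bins=nbins, range=s_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    empty = counts == 0
    with np.errstate(divide="ignore"):
        G = -kT * np.log(counts / counts.max())
    G[empty] = np.nan
    in_span = ~empty
    if span is not None:
        in_span &= (centers >= span[0]) & (centers <= span[1])
    if np.any(in_span):
        barrier = float(np.nanmax(G[in_span]) - np.nanmin(G[in_span]))
    else:
        barrier = float("nan")
    return FreeEnergyProfile(
        s=centers, G=G, counts=counts, barrier_height=barrier, empty_bins=empty
    )


def free_energy_profile(
    traj: Trajectory,
    pathway: Pathway,
    lipid_ids=None,
    tube_radius: float = 8.0,
    bin_width: float = 1.0,
    kT: float = 1.0,
    span: tuple[float, float] | None = None,
    min_observations: int = 1000,
) -> FreeEnergyProfile:
    """Invert the in-tube PO4 density along the pathway.

    Collects every (frame, lipid) observation of a PO4 bead within
    ``tube_radius`` of the pathway and histograms its z projection.
    ``span`` defaults to the membrane span between the leaflet surfaces
    so the barrier is read off the membrane-spanning region only.
    """
    if lipid_ids is None:
        lipid_ids = traj.lipid_resids()
    po4 = traj.select(name="PO4", resid=list(map(int, np.atleast_1d(lipid_ids))))
    pos = traj.coords[:, po4, :].reshape(-1, 3)
    lat = pathway.lateral_distance(pos)
    inside = (lat <= tube_radius) & (pos[:, 2] >= pathway.z_min) & (
        pos[:, 2] <= pathway.z_max
    )
    s_values = pos[inside, 2]
    if len(s_values) < min_observations:
        raise ValueError(
            f"only {len(s_values)} in-tube observations "
            f"(need >= {min_observations})"
        )
    if span is None:
        b = traj.metadata.get("bulk_thickness", 30.0)
        span = (-b / 2.0, b / 2.0)
    return FreeEnergyProfile(
        **dataclasses.asdict(
            profile_from_samples(
                s_values, bin_width=bin_width, kT=kT,
                s_range=(pathway.z_min, pathway.z_max), span=span,
            )
        )
    )


def estimate_diffusion(
    tracks: np.ndarray | list[np.ndarray],
    dt: float,
    lag_range: tuple[int, int] = (1, 10),
) -> tuple[float, float]:
    """MSD-based 1D diffusion coefficient.

    ``tracks`` is one 1D coordinate series or a list of them (angstrom).
    MSD(tau) is averaged over all time origins and tracks and fit through
    the origin as MSD = 2 D tau over the lag window.  Returns (D, stderr)
    in angstrom^2/ns.
    """
    if isinstance(tracks, np.ndarray) and tracks.ndim == 1:
        tracks = [tracks]
    lags = np.arange(lag_range[0], lag_range[1] + 1)
    msd = np.zeros(len(lags))
    weight = np.zeros(len(lags))
    for x in tracks:
        x = np.asarray(x, dtype=float)
        for k, lag in enumerate(lags):
            if len(x) > lag:
                d = x[lag:] - x[:-lag]
                msd[k] += np.sum(d * d)
                weight[k] += len(d)
    ok = weight > 0
    if not np.any(ok):
        raise ValueError("tracks shorter than the smallest lag")
    msd = msd[ok] / weight[ok]
    tau = lags[ok] * dt
    # least squares through the origin
    D = float(np.sum(msd * tau) / (2.0 * np.sum(tau * tau)))
    resid = msd - 2.0 * D * tau
    dof = max(1, len(tau) - 1)
    se = float(
        np.sqrt(np.sum(resid**2) / dof / np.sum(tau * tau)) / 2.0
    )
    return D, se


def transit_kinetics(
    events,
    traj: Trajectory,
    pathway: Pathway,
    tube_radius: float = 8.0,
    lag_range: tuple[int, int] = (1, 10),
    min_events_for_D: int = 5,
) -> TransitKinetics:
    """Per-event transit dwell times and the in-groove diffusion coefficient.

    The transit dwell of an event is the contiguous stretch of frames the
    lipid's PO4 bead spends inside the pathway tube containing the
    midplane crossing.  D is fit from the pooled MSD of the projected
    (z) coordinate within those windows.
    """
    dwells: list[float] = []
    windows: list[np.ndarray] = []
    z_mid = 0.5 * (pathway.z_min + pathway.z_max)
    for e in events:
        po4 = traj.select(resid=int(e.lipid_id), name="PO4")
        if len(po4) != 1:
            continue
        pos = traj.coords[:, po4[0], :]
        lat = pathway.lateral_distance(pos)
        inside = (lat <= tube_radius) & (pos[:, 2] >= pathway.z_min) & (
            pos[:, 2] <= pathway.z_max
        )
        f_c = int(round((e.t_complete - traj.t0) / traj.dt))
        # walk back to the midplane crossing nearest the completion frame
        z = pos[:, 2]
        sign_change = np.flatnonzero(np.diff(np.sign(z - z_mid)) != 0)
        if len(sign_change) == 0:
            continue
        f_cross = int(sign_change[np.argmin(np.abs(sign_change - f_c))])
        if not inside[f_cross]:
            continue
        a = f_cross
        while a > 0 and inside[a - 1]:
            a -= 1
        b = f_cross
        while b < len(inside) - 1 and inside[b + 1]:
            b += 1
        dwells.append((b - a + 1) * traj.dt)
        windows.append(z[a : b + 1])

    if len(dwells) >= min_events_for_D:
        D, se = estimate_diffusion(windows, traj.dt, lag_range)
        return TransitKinetics(dwells, D, se)
    return TransitKinetics(dwells, None, None)
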