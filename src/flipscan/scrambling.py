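"""Lipid flip-flop (scrambling) detection and rate statistics.

The orientation of each lipid is summarized by the angle between the
average of its NC3->C4A and NC3->C4B vectors and the +z axis: lipids
resting in the upper leaflet sit near 150 degrees, lower-leaflet lipids
near 30 degrees.  The raw per-frame angle is denoised with a centered
100 ns running average, and a hysteresis state machine counts a
scrambling event only when the smoothed angle of an upper-leaflet lipid
drops below 35 degrees (or a lower-leaflet lipid rises above 145), which
suppresses partial transitions that enter the band and return.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .model import Trajectory
from .pathway import Pathway

THETA_LOW = 35.0
THETA_HIGH = 145.0
SMOOTH_WINDOW_NS = 100.0


@dataclasses.dataclass
class AngleSeries:
    lipid_id: int
    t: np.ndarray  # ns
    theta_raw: np.ndarray  # degrees
    theta_smooth: np.ndarray  # degrees


@dataclasses.dataclass
class ScramblingEvent:
    lipid_id: int
    direction: str  # upper_to_lower | lower_to_upper
    t_complete: float  # ns, first smoothed frame past the threshold
    t_enter_band: float  # ns, last frame in the origin band before completing
    pathway_class: str = "unclassified"  # in_groove | out_of_groove | unclassified
    subunit: str | None = None


@dataclasses.dataclass
class RateEstimate:
    mean: float  # events / microsecond
    sd: float
    n_blocks: int
    block_length: float  # microseconds
    per_block_counts: list


@dataclasses.dataclass
class PoissonTestResult:
    n_events: int
    ks_statistic: float | None
    p_value: float | None
    dispersion_index: float | None
    verdict: str  # consistent | inconsistent | undefined


def smooth_angles(theta: np.ndarray, dt: float,
                  window_ns: float = SMOOTH_WINDOW_NS) -> np.ndarray:
    """Centered moving average, window truncated at the series edges."""
    w = max(1, min(int(round(window_ns / dt)), len(theta)))
    kernel = np.ones(w)
    num = np.convolve(theta, kernel, mode="same")
    den = np.convolve(np.ones_like(theta), kernel, mode="same")
    return num / den


def lipid_orientation_angles(
    traj: Trajectory, window_ns: float = SMOOTH_WINDOW_NS
) -> list[AngleSeries]:
    """Per-lipid orientation-angle series, raw and smoothed."""
    out: list[AngleSeries] = []
    lip_ids = traj.lipid_resids()
    nc3 = traj.select(name="NC3")
    c4a = traj.select(name="C4A")
    c4b = traj.select(name="C4B")
    by_resid = {}
    for arr, key in ((nc3, "NC3"), (c4a, "C4A"), (c4b, "C4B")):
        for i in arr:
            by_resid.setdefault(int(traj.resids[i]), {})[key] = i
    t = traj.times
    for lid in lip_ids:
        beads = by_resid.get(int(lid), {})
        missing = [k for k in ("NC3", "C4A", "C4B") if k not in beads]
        if missing:
            raise ValueError(
                f"lipid {lid} is missing bead(s) {', '.join(missing)}"
            )
        v = 0.5 * (
            (traj.coords[:, beads["C4A"], :] - traj.coords[:, beads["NC3"], :])
            + (traj.coords[:, beads["C4B"], :] - traj.coords[:, beads["NC3"], :])
        )
        norm = np.linalg.norm(v, axis=1)
        cos = np.clip(v[:, 2] / np.maximum(norm, 1e-12), -1.0, 1.0)
        theta = np.degrees(np.arccos(cos))
        out.append(
            AngleSeries(
                lipid_id=int(lid),
                t=t,
                theta_raw=theta,
                theta_smooth=smooth_angles(theta, traj.dt, window_ns),
            )
        )
    return out


def detect_events(
    series: AngleSeries,
    theta_low: float = THETA_LOW,
    theta_high: float = THETA_HIGH,
    return_states: bool = False,
):
    """Hysteresis detection of completed leaflet transitions.

    The lipid starts in the leaflet indicated by its first smoothed angle
    (upper if > 90 degrees).  An upper-state lipid emits an
    ``upper_to_lower`` event at the first frame with smoothed angle below
    ``theta_low`` and flips state; symmetric for ``lower_to_upper`` above
    ``theta_high``.  Excursions into the band that return emit nothing.

    With ``return_states`` the per-frame leaflet state (+1 upper,
    -1 lower) is returned alongside the events; the surface module uses it
    for per-frame leaflet assignment.
    """
    th = series.theta_smooth
    t = series.t
    state = 1 if th[0] > 90.0 else -1
    events: list[ScramblingEvent] = []
    states = np.empty(len(th), dtype=np.int8) if return_states else None

    # only frames beyond a threshold can change the state
    marks = np.where(th < theta_low, -1, np.where(th > theta_high, 1, 0))
    hot = np.flatnonzero(marks)
    last_band_frame = {1: None, -1: None}  # last frame seen in each pole band
    prev = 0
    for f in hot:
        m = marks[f]
        if states is not None:
            states[prev:f] = state
        if m == -1:
            if state == 1:
                origin = last_band_frame[1]
                events.append(
                    ScramblingEvent(
                        lipid_id=series.lipid_id,
                        direction="upper_to_lower",
                        t_complete=float(t[f]),
                        t_enter_band=float(t[origin] if origin is not None else t[0]),
                    )
                )
                state = -1
            last_band_frame[-1] = f
        else:
            if state == -1:
                origin = last_band_frame[-1]
                events.append(
                    ScramblingEvent(
                        lipid_id=series.lipid_id,
                        direction="lower_to_upper",
                        t_complete=float(t[f]),
                        t_enter_band=float(t[origin] if origin is not None else t[0]),
                    )
                )
                state = 1
            last_band_frame[1] = f
        prev = f
    if states is not None:
        states[prev:] = state
        return events, states
    return events


def detect_all_events(
    traj: Trajectory,
    theta_low: float = THETA_LOW,
    theta_high: float = THETA_HIGH,
    window_ns: float = SMOOTH_WINDOW_NS,
):
    """Angles + detection over every lipid; returns (series, events, states).

    ``states`` is an ``(n_lipids, n_frames)`` int8 array of per-frame
    leaflet states, ordered like ``traj.lipid_resids()``.
    """
    series = lipid_orientation_angles(traj, window_ns)
    all_events: list[ScramblingEvent] = []
    states = np.empty((len(series), traj.n_frames), dtype=np.int8)
    for i, s in enumerate(series):
        ev, st = detect_events(s, theta_low, theta_high, return_states=True)
        all_events.extend(ev)
        states[i] = st
    all_events.sort(key=lambda e: e.t_complete)
    return series, all_events, states


def classify_pathway(
    event: ScramblingEvent,
    traj: Trajectory,
    pathway: Pathway | dict[str, Pathway] | None,
    r: float = 4.7,
    membrane_span: float | None = None,
) -> str:
    """In-groove / out-of-groove classification of one event.

    The event is ``in_groove`` iff, between leaving the origin leaflet
    band and completing the transition, the lipid's PO4 bead comes within
    ``r`` of any pathway node while its z lies within the middle half of
    the membrane span.  A dict of per-subunit pathways classifies against
    each and records the nearest subunit.
    """
    if pathway is None:
        event.pathway_class = "unclassified"
        return event.pathway_class
    pathways = pathway if isinstance(pathway, dict) else {None: pathway}
    if membrane_span is None:
        membrane_span = traj.metadata.get("bulk_thickness", 30.0)
    po4 = traj.select(resid=int(event.lipid_id), name="PO4")
    if len(po4) != 1:
        raise ValueError(f"lipid {event.lipid_id} lacks a unique PO4 bead")
    f_a = int(round((event.t_enter_band - traj.t0) / traj.dt))
    f_b = int(round((event.t_complete - traj.t0) / traj.dt))
    pos = traj.coords[f_a : f_b + 1, po4[0], :]
    mid = np.abs(pos[:, 2]) <= membrane_span / 4.0
    best: tuple[float, str | None] | None = None
    for sub, pw in pathways.items():
        if not np.any(mid):
            continue
        d = pw.distance_to(pos[mid])
        dmin = float(d.min())
        if best is None or dmin < best[0]:
            best = (dmin, sub)
    if best is not None and best[0] <= r:
        event.pathway_class = "in_groove"
        event.subunit = best[1]
    else:
        event.pathway_class = "out_of_groove"
        event.subunit = best[1] if best is not None else None
    return event.pathway_class


def classify_events(events, traj, pathway, r: float = 4.7,
                    membrane_span: float | None = None):
    for e in events:
        classify_pathway(e, traj, pathway, r=r, membrane_span=membrane_span)
    return events


def block_rate(
    events,
    duration: float,
    block: float = 1000.0,
    t0: float = 0.0,
) -> RateEstimate:
    """Block-averaged scrambling rate in events per microsecond.

    Non-overlapping blocks of ``block`` ns starting at ``t0``; the
    trailing partial block is discarded.  The spread is the population
    standard deviation over blocks.
    """
    if duration < block:
        raise ValueError(f"duration {duration} ns < block length {block} ns")
    n_blocks = int(duration // block)
    t_times = np.asarray(
        [e.t_complete if isinstance(e, ScramblingEvent) else float(e) for e in events]
    )
    counts = np.zeros(n_blocks, dtype=int)
    if len(t_times):
        bi = ((t_times - t0) // block).astype(int)
        ok = (bi >= 0) & (bi < n_blocks)
        np.add.at(counts, bi[ok], 1)
    block_us = block / 1000.0
    mean = counts.sum() / (n_blocks * block_us)
    sd = float(np.std(counts, ddof=0) / block_us)
    return RateEstimate(
        mean=float(mean), sd=sd, n_blocks=n_blocks,
        block_length=block_us, per_block_counts=counts.tolist(),
    )


def poisson_test(
    events, duration: float, t0: float = 0.0, block: float = 1000.0,
    alpha: float = 0.05,
) -> PoissonTestResult:
    """Two complementary diagnostics of Poisson (memoryless) scrambling.

    A Kolmogorov-Smirnov test of inter-event gaps against an exponential
    with rate n/duration, plus the dispersion index (variance/mean) of
    1 us block counts.  The verdict is ``consistent`` iff the KS p-value
    is at least ``alpha``; fewer than 2 events give no verdict.
    """
    t_times = np.sort(np.asarray(
        [e.t_complete if isinstance(e, ScramblingEvent) else float(e) for e in events]
    ))
    n = len(t_times)
    if n < 2:
        return PoissonTestResult(n, None, None, None, "undefined")
    gaps = np.diff(t_times)
    scale = duration / n  # mean gap under the fitted-rate null
    ks = stats.kstest(gaps, "expon", args=(0.0, scale))
    n_blocks = max(1, int(duration // block))
    counts = np.zeros(n_blocks)
    bi = ((t_times - t0) // block).astype(int)
    ok = (bi >= 0) & (bi < n_blocks)
    np.add.at(counts, bi[ok], 1)
    disp = float(np.var(counts) / counts.mean()) if counts.mean() > 0 else None
    verdict = "consistent" if ks.pvalue >= alpha else "inconsistent"
    return PoissonTestResult(
        n_events=n,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        dispersion_index=disp,
        verdict=verdict,
    )
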