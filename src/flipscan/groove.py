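"""TM4-TM6 groove width dynamics and scrambling-competence gating.

The groove width is the frame-wise minimum distance between any two beads
of the TM4 and TM6 residue ranges.  The raw series feeds the median and
quartiles; a recursively exponentially weighted moving average (EWMA,
smoothing factor 0.1) feeds the binary open/closed flag at the 6 A
threshold.  A structure is scrambling-competent when its membrane is
pinched below 14 A *and* its median groove width exceeds 6 A.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.distance import cdist

from .model import Trajectory

#: TM4/TM6 residue ranges per homolog.  The published TMEM16F TM4 range
#: reads "512-424", an apparent transposition; 512-524 is used here.
HOMOLOG_RANGES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "nhTMEM16": ((327, 339), (430, 452)),
    "afTMEM16": ((319, 331), (426, 438)),
    "TMEM16K": ((365, 377), (434, 446)),
    "TMEM16F": ((512, 524), (613, 625)),
    "TMEM16A": ((541, 553), (635, 647)),
}

OPEN_THRESHOLD = 6.0  # angstrom, on the smoothed series
EWMA_ALPHA = 0.1
THICKNESS_GATE = 14.0  # angstrom


@dataclasses.dataclass(frozen=True)
class GrooveSpec:
    tm4_residues: tuple[int, int]
    tm6_residues: tuple[int, int]
    chain_id: str = "A"

    @classmethod
    def for_homolog(cls, name: str, chain_id: str = "A") -> "GrooveSpec":
        tm4, tm6 = HOMOLOG_RANGES[name]
        return cls(tm4, tm6, chain_id)


@dataclasses.dataclass
class GrooveSeries:
    t: np.ndarray
    d_raw: np.ndarray
    d_smooth: np.ndarray
    open_flag: np.ndarray
    chain_id: str = "A"


@dataclasses.dataclass
class GrooveStats:
    median: float
    q1: float
    q3: float
    open_fraction: float
    events_while_open: int


def ewma(x: np.ndarray, alpha: float = EWMA_ALPHA) -> np.ndarray:
    """s_t = alpha * x_t + (1 - alpha) * s_{t-1}, s_0 = x_0."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return x.copy()
    # IIR filter form; zi primes the recursion so that s_0 == x_0
    out = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])[0]
    return out


def groove_distance_series(
    traj: Trajectory,
    spec: GrooveSpec,
    alpha: float = EWMA_ALPHA,
    open_threshold: float = OPEN_THRESHOLD,
    chunk: int = 500,
) -> GrooveSeries:
    """Frame-wise minimum TM4-TM6 bead-pair distance, raw and EWMA-smoothed.

    All beads (backbone and side chain) of the listed residues enter the
    minimum.
    """
    i4 = traj.select(chain=spec.chain_id, resid=spec.tm4_residues)
    i6 = traj.select(chain=spec.chain_id, resid=spec.tm6_residues)
    if len(i4) == 0 or len(i6) == 0:
        raise ValueError(
            f"groove residue range resolves to no beads "
            f"(TM4: {len(i4)}, TM6: {len(i6)}) on chain {spec.chain_id!r}"
        )
    F = traj.n_frames
    d_raw = np.empty(F)
    for f0 in range(0, F, chunk):
        f1 = min(F, f0 + chunk)
        a = traj.coords[f0:f1, i4, :]
        b = traj.coords[f0:f1, i6, :]
        for k in range(f1 - f0):
            d_raw[f0 + k] = cdist(a[k], b[k]).min()
    d_smooth = ewma(d_raw, alpha)
    return GrooveSeries(
        t=traj.times,
        d_raw=d_raw,
        d_smooth=d_smooth,
        open_flag=d_smooth > open_threshold,
        chain_id=spec.chain_id,
    )


def groove_stats(series: GrooveSeries, events=()) -> GrooveStats:
    """Quartiles of the raw width, open fraction, and events completed
    while the groove was open."""
    if len(series.d_raw) == 0:
        raise ValueError("empty groove series")
    q1, med, q3 = np.percentile(series.d_raw, [25, 50, 75])
    open_fraction = float(np.mean(series.open_flag))
    n_open = 0
    if len(series.t) and len(events):
        dt = series.t[1] - series.t[0] if len(series.t) > 1 else 1.0
        for e in events:
            tc = e.t_complete if hasattr(e, "t_complete") else float(e)
            f = int(round((tc - series.t[0]) / dt))
            if 0 <= f < len(series.open_flag) and series.open_flag[f]:
                n_open += 1
    return GrooveStats(
        median=float(med), q1=float(q1), q3=float(q3),
        open_fraction=open_fraction, events_while_open=n_open,
    )


def classify_competence(
    min_thickness: float,
    median_width: float,
    thickness_gate: float = THICKNESS_GATE,
    width_gate: float = OPEN_THRESHOLD,
) -> str:
    """Thickness-width quadrant gate for robust scrambling.

    Strict inequalities: values exactly at the 14 A / 6 A boundaries are
    classified non-competent.
    """
    if min_thickness <= 0 or median_width <= 0:
        raise ValueError("thickness and width must be positive")
    competent = (min_thickness < thickness_gate) and (median_width > width_gate)
    return "competent" if competent else "non_competent"
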