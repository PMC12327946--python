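"""Protein-lipid headgroup contacts and dwell-time statistics.

A contact is a distance below 7 A between a residue's outermost
side-chain bead (backbone bead for glycine) and a lipid's choline (NC3)
or phosphate (PO4) bead.  Dwell times merge contact runs separated by
gaps of at most 6 ns, and each residue is summarized with the headgroup
bead that yields the higher mean dwell time; the top-50% mean keeps the
ceil(n/2) longest dwells.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import Trajectory

CONTACT_CUTOFF = 7.0  # angstrom, strict <
GAP_TOLERANCE = 6.0  # ns


@dataclasses.dataclass
class ContactSeries:
    residue_id: int
    lipid_id: int
    bead: str  # NC3 | PO4
    contact: np.ndarray  # (F,) bool


@dataclasses.dataclass
class DwellSummary:
    residue_id: int
    chain_id: str
    contact_frequency: float
    dwell_list: list
    mean_dwell: float
    top50_mean_dwell: float
    chosen_bead: str
    no_contact: bool = False


def outermost_sidechain_bead(traj: Trajectory, residue_id: int,
                             chain_id: str = "A") -> int:
    """Index of the residue's outermost side-chain bead.

    "Outermost" is the side-chain bead with the largest mean distance
    from the residue's backbone bead over the trajectory; glycine (no
    side chain) falls back to the backbone bead itself.
    """
    beads = traj.select(chain=chain_id, resid=int(residue_id))
    if len(beads) == 0:
        raise ValueError(f"residue {residue_id} (chain {chain_id}) has no beads")
    bb = [i for i in beads if traj.names[i] == "BB"]
    sc = [i for i in beads if traj.names[i].startswith("SC")]
    if not sc:
        return int(bb[0] if bb else beads[0])
    if not bb:
        return int(sc[0])
    d = [
        float(np.mean(np.linalg.norm(
            traj.coords[:, i, :] - traj.coords[:, bb[0], :], axis=1)))
        for i in sc
    ]
    return int(sc[int(np.argmax(d))])


def contact_series(
    traj: Trajectory,
    residue_id: int,
    bead_choice: str,
    chain_id: str = "A",
    cutoff: float = CONTACT_CUTOFF,
    lipid_ids=None,
) -> list[ContactSeries]:
    """Per-lipid boolean contact series for one residue and one headgroup bead."""
    if bead_choice not in ("NC3", "PO4"):
        raise ValueError("bead_choice must be NC3 or PO4")
    ri = outermost_sidechain_bead(traj, residue_id, chain_id)
    rpos = traj.coords[:, ri, :]
    if lipid_ids is None:
        lipid_ids = traj.lipid_resids()
    head_idx = traj.select(name=bead_choice)
    by_resid = {int(traj.resids[i]): i for i in head_idx}
    out = []
    for lid in lipid_ids:
        hi = by_resid.get(int(lid))
        if hi is None:
            continue
        d = np.linalg.norm(traj.coords[:, hi, :] - rpos, axis=1)
        out.append(
            ContactSeries(
                residue_id=int(residue_id), lipid_id=int(lid),
                bead=bead_choice, contact=d < cutoff,
            )
        )
    return out


def dwell_times(
    contact: np.ndarray | ContactSeries,
    dt: float = 1.0,
    gap_tolerance: float = GAP_TOLERANCE,
) -> list[float]:
    """Dwell durations (ns) after merging runs across short gaps.

    Runs of contact separated by gaps of at most ``gap_tolerance`` ns are
    one dwell; the duration counts both endpoint frames
    ((last - first + 1) * dt).
    """
    c = contact.contact if isinstance(contact, ContactSeries) else np.asarray(contact)
    c = c.astype(bool)
    if not c.any():
        return []
    idx = np.flatnonzero(c)
    # run starts/ends in frame indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    max_gap_frames = int(np.floor(gap_tolerance / dt + 1e-9))
    dwells = []
    cur_start, cur_end = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s - cur_end - 1 <= max_gap_frames:
            cur_end = e
        else:
            dwells.append((cur_end - cur_start + 1) * dt)
            cur_start, cur_end = s, e
    dwells.append((cur_end - cur_start + 1) * dt)
    return [float(d) for d in dwells]


def _dwells_for_bead(traj, residue_id, bead, chain_id, cutoff, gap_tolerance,
                     lipid_ids):
    series = contact_series(traj, residue_id, bead, chain_id, cutoff, lipid_ids)
    dwells: list[float] = []
    any_contact = np.zeros(traj.n_frames, dtype=bool)
    for s in series:
        dwells.extend(dwell_times(s, traj.dt, gap_tolerance))
        any_contact |= s.contact
    return dwells, any_contact


def residue_summary(
    traj: Trajectory,
    residue_id: int,
    chain_ids: tuple[str, ...] = ("A",),
    cutoff: float = CONTACT_CUTOFF,
    gap_tolerance: float = GAP_TOLERANCE,
    lipid_ids=None,
) -> DwellSummary:
    """Per-residue summary with the bead-choice and top-50% rules.

    Contact frequency is the fraction of frames with at least one lipid
    in contact, averaged over the listed chains (monomers).  Dwell lists
    from all chains are pooled for the chosen bead.
    """
    per_bead: dict[str, list[float]] = {}
    freq_by_chain: dict[str, dict[str, float]] = {}
    for bead in ("NC3", "PO4"):
        dwells_all: list[float] = []
        for ch in chain_ids:
            dw, any_c = _dwells_for_bead(
                traj, residue_id, bead, ch, cutoff, gap_tolerance, lipid_ids
            )
            dwells_all.extend(dw)
            freq_by_chain.setdefault(bead, {})[ch] = float(np.mean(any_c))
        per_bead[bead] = dwells_all

    means = {b: (np.mean(d) if d else 0.0) for b, d in per_bead.items()}
    chosen = "NC3" if means["NC3"] >= means["PO4"] else "PO4"
    dwells = sorted(per_bead[chosen], reverse=True)
    freq = float(np.mean(list(freq_by_chain[chosen].values())))
    if not dwells:
        return DwellSummary(
            residue_id=int(residue_id), chain_id=",".join(chain_ids),
            contact_frequency=freq, dwell_list=[], mean_dwell=0.0,
            top50_mean_dwell=0.0, chosen_bead=chosen, no_contact=True,
        )
    n_top = int(np.ceil(len(dwells) / 2))
    return DwellSummary(
        residue_id=int(residue_id), chain_id=",".join(chain_ids),
        contact_frequency=freq, dwell_list=dwells,
        mean_dwell=float(np.mean(dwells)),
        top50_mean_dwell=float(np.mean(dwells[:n_top])),
        chosen_bead=chosen,
    )


def summarize_residues(
    traj: Trajectory,
    residue_ids,
    chain_ids: tuple[str, ...] = ("A",),
    **kwargs,
):
    """DataFrame of :func:`residue_summary` over many residues."""
    import pandas as pd

    rows = []
    for rid in residue_ids:
        s = residue_summary(traj, rid, chain_ids, **kwargs)
        rows.append(
            {
                "residue": s.residue_id,
                "frequency": s.contact_frequency,
                "mean_dwell": s.mean_dwell,
                "top50_mean_dwell": s.top50_mean_dwell,
                "chosen_bead": s.chosen_bead,
                "n_dwells": len(s.dwell_list),
            }
        )
    return pd.DataFrame(rows)
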