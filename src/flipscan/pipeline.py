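"""End-to-end orchestration of the analysis stages.

``run_all`` executes the stages in dependency order on either a loaded
trajectory or a freshly generated synthetic one, writes every
intermediate table/grid under the output directory, and returns a
consolidated report.  ``validate_against_truth`` checks a report (plus
the stage outputs it references) against a synthetic ground truth.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from . import density as density_mod
from . import groove as groove_mod
from . import kinetics as kinetics_mod
from . import permeation as permeation_mod
from . import scrambling as scrambling_mod
from . import surface as surface_mod
from .config import AnalysisConfig, save_config
from .io import discard_equilibration, load_trajectory, write_json
from .model import Trajectory
from .synth import GroundTruth, SyntheticSpec, build_system


@dataclasses.dataclass
class Report:
    """Consolidated per-run numbers; every field traces to a stage file."""

    n_events: int = 0
    rate_mean: float = 0.0
    rate_sd: float = 0.0
    n_in_groove: int = 0
    n_out_of_groove: int = 0
    n_unclassified: int = 0
    poisson_verdict: str = "undefined"
    median_width: float = float("nan")
    q1_width: float = float("nan")
    q3_width: float = float("nan")
    open_fraction: float = float("nan")
    events_while_open: int = 0
    min_thickness: float = float("nan")
    min_thickness_groove: float = float("nan")
    competence: str = "non_competent"
    permeation: dict = dataclasses.field(default_factory=dict)
    selectivity: float = float("nan")
    barrier_kT: float = float("nan")
    diffusion: float | None = None
    mean_transit_dwell: float = float("nan")
    events: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _get_trajectory(cfg: AnalysisConfig) -> tuple[Trajectory, GroundTruth | None]:
    if cfg.synthetic is not None:
        kwargs = dict(cfg.synthetic)
        kwargs.setdefault("seed", cfg.seed)
        spec = _spec_from_dict(kwargs)
        return build_system(spec)
    if cfg.topology is None:
        raise ValueError("config needs either synthetic parameters or a topology")
    if not os.path.exists(cfg.topology) or (
        cfg.trajectory is not None and not os.path.exists(cfg.trajectory)
    ):
        raise FileNotFoundError("topology/trajectory path does not exist")
    return load_trajectory(cfg.topology, cfg.trajectory), None


def _spec_from_dict(kwargs: dict) -> SyntheticSpec:
    from . import synth

    def _coerce(cls, value):
        return cls(**value) if isinstance(value, dict) else value

    for key, cls in (
        ("deformation", synth.DeformationSpec),
        ("scaffold", synth.ScaffoldSpec),
        ("breathing", synth.BreathingSpec),
    ):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = _coerce(cls, kwargs[key])
    for key in ("box",):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "flip_schedule" in kwargs:
        kwargs["flip_schedule"] = tuple(
            tuple(e) for e in kwargs["flip_schedule"]
        )
    if "contact_spec" in kwargs:
        kwargs["contact_spec"] = tuple(
            synth.ContactPlan(**p) if isinstance(p, dict) else p
            for p in kwargs["contact_spec"]
        )
    if "tracer_spec" in kwargs:
        kwargs["tracer_spec"] = tuple(
            synth.TracerTransit(**t) if isinstance(t, dict) else t
            for t in kwargs["tracer_spec"]
        )
    return SyntheticSpec(**kwargs)


def run_all(cfg: AnalysisConfig, traj: Trajectory | None = None,
            truth: GroundTruth | None = None) -> Report:
    cfg.validate()
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    save_config(cfg, os.path.join(outdir, "config_echo.toml"))

    if traj is None:
        traj, truth = _get_trajectory(cfg)
    if cfg.t_eq > 0:
        traj = discard_equilibration(traj, cfg.t_eq)

    report = Report()

    # ---- scrambling ----------------------------------------------------
    series, events, states = scrambling_mod.detect_all_events(
        traj, cfg.theta_low, cfg.theta_high, cfg.smooth_window
    )
    report.n_events = len(events)
    rate = scrambling_mod.block_rate(
        events, duration=traj.duration,
        block=min(cfg.block, traj.duration), t0=traj.t0,
    )
    report.rate_mean, report.rate_sd = rate.mean, rate.sd
    pd.DataFrame(
        {"block": range(rate.n_blocks), "count": rate.per_block_counts}
    ).to_csv(os.path.join(outdir, "rates.csv"), index=False)
    pois = scrambling_mod.poisson_test(events, traj.duration, t0=traj.t0,
                                       block=cfg.block)
    report.poisson_verdict = pois.verdict

    # ---- densities and pathway ----------------------------------------
    b = traj.metadata.get("bulk_thickness", 30.0)
    extents = cfg.density_extents
    head_grid = density_mod.accumulate_density(
        traj, role="lipid_head", spacing=cfg.density_grid, extents=extents
    )
    density_mod.export_grid(head_grid, os.path.join(outdir, "density_headgroup.dx"))
    n_water = len(traj.select(role="water"))
    pathway = None
    z_span = (-b / 2.0 - cfg.z_margin, b / 2.0 + cfg.z_margin)
    if n_water:
        water_grid = density_mod.accumulate_density(
            traj, role="water", spacing=cfg.density_grid, extents=extents
        )
        density_mod.export_grid(water_grid, os.path.join(outdir, "density_water.dx"))
        try:
            pathway = density_mod.extract_pathway(water_grid, z_range=z_span)
        except ValueError:
            pathway = None
    if pathway is None:
        pathway = traj.metadata.get("pathways", {}).get("groove_axis")
    if pathway is not None:
        write_json(pathway.to_dict(), os.path.join(outdir, "pathway.json"))

    scrambling_mod.classify_events(
        events, traj, pathway, r=cfg.pathway_radius, membrane_span=b
    )
    report.n_in_groove = sum(e.pathway_class == "in_groove" for e in events)
    report.n_out_of_groove = sum(e.pathway_class == "out_of_groove" for e in events)
    report.n_unclassified = sum(e.pathway_class == "unclassified" for e in events)
    report.events = [dataclasses.asdict(e) for e in events]
    write_json(report.events, os.path.join(outdir, "events.json"))

    # ---- surfaces and thickness ----------------------------------------
    labels = surface_mod.assign_leaflets(traj, states)
    sp = surface_mod.average_surfaces(
        traj, labels, spacing=cfg.surface_grid, occupancy_min=cfg.occupancy_min
    )
    surface_mod.surfaces_to_table(sp).to_csv(
        os.path.join(outdir, "surfaces.csv"), index=False
    )
    mt = surface_mod.minimal_thickness(sp)
    report.min_thickness = mt.value
    gc = traj.metadata.get("groove_center", (0.0, 0.0))
    try:
        mt_g = surface_mod.minimal_thickness(sp, region_center=gc, region_radius=25.0)
        report.min_thickness_groove = mt_g.value
    except ValueError:
        report.min_thickness_groove = mt.value
    write_json(
        {
            "global": {"value": mt.value,
                       "point_upper": mt.point_upper, "point_lower": mt.point_lower},
            "groove_region": {"value": report.min_thickness_groove},
        },
        os.path.join(outdir, "min_thickness.json"),
    )

    # ---- groove geometry ----------------------------------------------
    stats_rows = []
    groove_series = {}
    for ch in cfg.groove_chains:
        gspec = groove_mod.GrooveSpec(tuple(cfg.tm4), tuple(cfg.tm6), ch)
        try:
            gs = groove_mod.groove_distance_series(
                traj, gspec, alpha=cfg.ewma_alpha, open_threshold=cfg.groove_open
            )
        except ValueError:
            continue
        groove_series[ch] = gs
        st = groove_mod.groove_stats(gs, events)
        stats_rows.append(
            {"chain": ch, "median": st.median, "q1": st.q1, "q3": st.q3,
             "open_fraction": st.open_fraction,
             "events_while_open": st.events_while_open}
        )
    if groove_series:
        pd.concat(
            [
                pd.DataFrame(
                    {"t": gs.t, "chain": ch, "d_raw": gs.d_raw,
                     "d_smooth": gs.d_smooth, "open": gs.open_flag}
                )
                for ch, gs in groove_series.items()
            ],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "groove.csv"), index=False)
        best = max(stats_rows, key=lambda r: r["median"])
        report.median_width = best["median"]
        report.q1_width, report.q3_width = best["q1"], best["q3"]
        report.open_fraction = best["open_fraction"]
        report.events_while_open = best["events_while_open"]
        write_json(stats_rows, os.path.join(outdir, "groove_stats.json"))
        report.competence = groove_mod.classify_competence(
            report.min_thickness, report.median_width,
            cfg.thickness_gate, cfg.groove_open,
        )
        write_json(
            {"min_thickness": report.min_thickness,
             "median_width": report.median_width,
             "competence": report.competence},
            os.path.join(outdir, "competence.json"),
        )

    # ---- contacts ------------------------------------------------------
    if cfg.contact_residues:
        df = contacts_mod.summarize_residues(
            traj, cfg.contact_residues, chain_ids=tuple(cfg.groove_chains),
            cutoff=cfg.contact_cutoff, gap_tolerance=cfg.gap_tolerance,
        )
        df.to_csv(os.path.join(outdir, "contacts.csv"), index=False)

    # ---- permeation ----------------------------------------------------
    if pathway is not None:
        perm_rows = []
        counts = {}
        for sp_name in ("water", "Na", "Cl"):
            c = permeation_mod.count_permeation(
                traj, sp_name, pathway, tube_radius=cfg.tube_radius,
                z_bounds=(-b / 2.0, b / 2.0), z_margin=cfg.z_margin,
            )
            counts[sp_name] = c
            report.permeation[sp_name] = {
                "up": c.up_count, "down": c.down_count, "total": c.total,
                "net": c.net, "rate_per_us": c.rate_per_us,
            }
            perm_rows.append(
                {"species": sp_name, "up": c.up_count, "down": c.down_count,
                 "total": c.total, "rate_per_us": c.rate_per_us}
            )
        pd.DataFrame(perm_rows).to_csv(
            os.path.join(outdir, "permeation.csv"), index=False
        )
        sel = permeation_mod.selectivity(counts["Na"], counts["Cl"])
        report.selectivity = sel.p_na_over_cl
        write_json(
            {"p_na_over_cl": None if np.isnan(sel.p_na_over_cl) else sel.p_na_over_cl,
             "n_na": sel.n_na, "n_cl": sel.n_cl},
            os.path.join(outdir, "selectivity.json"),
        )

    # ---- kinetics ------------------------------------------------------
    if pathway is not None:
        in_groove = [e for e in events if e.pathway_class == "in_groove"]
        try:
            prof = kinetics_mod.free_energy_profile(
                traj, pathway,
                lipid_ids=[e["lipid_id"] if isinstance(e, dict) else e.lipid_id
                           for e in in_groove] or None,
                tube_radius=cfg.tube_radius, bin_width=cfg.fe_bin,
            )
            report.barrier_kT = prof.barrier_height
            pd.DataFrame(
                {"s": prof.s, "G_kT": prof.G, "counts": prof.counts}
            ).to_csv(os.path.join(outdir, "free_energy.csv"), index=False)
        except ValueError:
            pass
        tk = kinetics_mod.transit_kinetics(
            in_groove, traj, pathway, tube_radius=cfg.tube_radius,
            lag_range=tuple(cfg.lag_range),
        )
        report.diffusion = tk.D_estimate
        if tk.transit_dwell_list:
            report.mean_transit_dwell = float(np.mean(tk.transit_dwell_list))
        write_json(
            {"transit_dwells_ns": tk.transit_dwell_list,
             "D_A2_per_ns": tk.D_estimate, "D_stderr": tk.D_stderr},
            os.path.join(outdir, "kinetics.json"),
        )

    out = report.to_dict()
    write_json(out, os.path.join(outdir, "report.json"))
    flat = {k: v for k, v in out.items() if not isinstance(v, (dict, list))}
    pd.DataFrame([flat]).to_csv(os.path.join(outdir, "report.csv"), index=False)
    return report


# -- validation ----------------------------------------------------------

@dataclasses.dataclass
class ValidationSummary:
    checks: list
    passed: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_against_truth(
    report: Report | dict,
    truth: GroundTruth | None,
    thickness_tol: float = 1.5,
    t_complete_tol: float = 75.0,
    duty_tol: float = 0.02,
) -> ValidationSummary:
    """Compare a report with the generator's ground truth.

    Checks event counts, identities and directions, pathway labels,
    minimal thickness against the analytic value, permeation counts and
    (when a breathing groove was programmed) the open fraction.
    """
    rep = report.to_dict() if isinstance(report, Report) else dict(report)
    checks: list[dict] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"name": name, "passed": bool(passed), "detail": detail})

    if truth is None or (not truth.events and not truth.planted_crossings
                         and truth.open_duty is None):
        check("ground_truth_present", True, "empty ground truth; validation skipped")
        return ValidationSummary(checks, True)

    ev = rep.get("events", [])
    check(
        "event_count", len(ev) == len(truth.events),
        f"detected {len(ev)}, planted {len(truth.events)}",
    )
    det = sorted((e["lipid_id"], e["direction"]) for e in ev)
    plan = sorted((e.lipid_id, e.direction) for e in truth.events)
    check("event_identities", det == plan)
    def _times_by_key(pairs):
        out: dict = {}
        for key, t in pairs:
            out.setdefault(key, []).append(t)
        return {k: sorted(v) for k, v in out.items()}

    det_t = _times_by_key(
        ((e["lipid_id"], e["direction"]), e["t_complete"]) for e in ev
    )
    plan_t = _times_by_key(
        ((e.lipid_id, e.direction), e.t_complete) for e in truth.events
    )
    t_ok = det_t.keys() == plan_t.keys() and all(
        len(det_t[k]) == len(plan_t[k])
        and all(abs(a - b) <= t_complete_tol
                for a, b in zip(det_t[k], plan_t[k]))
        for k in plan_t
    )
    check("completion_times", t_ok, f"tolerance {t_complete_tol} ns")
    n_in = sum(e.label == "in_groove" for e in truth.events)
    n_out = len(truth.events) - n_in
    check(
        "pathway_labels",
        rep.get("n_in_groove") == n_in and rep.get("n_out_of_groove") == n_out,
        f"planted {n_in} in / {n_out} out; "
        f"found {rep.get('n_in_groove')} / {rep.get('n_out_of_groove')}",
    )
    mt = rep.get("min_thickness_groove", rep.get("min_thickness"))
    if truth.events:
        # scrambling lipids bridge the leaflets and thin the measured
        # surfaces beyond the deformation field, so the analytic value is
        # an upper bound rather than an equality
        ok_mt = mt <= truth.analytic_min_thickness + thickness_tol
    else:
        ok_mt = abs(mt - truth.analytic_min_thickness) <= thickness_tol
    check(
        "min_thickness", ok_mt,
        f"measured {mt:.2f} vs analytic {truth.analytic_min_thickness:.2f}",
    )
    if truth.planted_crossings:
        perm = rep.get("permeation", {})
        ok = True
        detail = []
        for sp_name, planted in truth.planted_crossings.items():
            got = perm.get(sp_name, {})
            ok &= got.get("up") == planted.get("up", 0)
            ok &= got.get("down") == planted.get("down", 0)
            detail.append(f"{sp_name}: {got.get('up')}/{got.get('down')} "
                          f"vs {planted.get('up', 0)}/{planted.get('down', 0)}")
        check("permeation_counts", ok, "; ".join(detail))
    if truth.open_duty is not None:
        of = rep.get("open_fraction")
        check(
            "open_fraction",
            of is not None and abs(of - truth.open_duty) <= duty_tol,
            f"measured {of} vs programmed {truth.open_duty}",
        )
    return ValidationSummary(checks, all(c["passed"] for c in checks))
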