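"""Run configuration with documented threshold defaults.

Every threshold default corresponds to the standard protocol for
quantifying scrambling in coarse-grained TMEM16 simulations; the
``PROVENANCE`` table says what each one means and in which analysis it is
used, and is echoed next to the values whenever a config is written, so
that an output directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import os
import tomllib


@dataclasses.dataclass
class AnalysisConfig:
    # inputs
    topology: str | None = None
    trajectory: str | None = None
    synthetic: dict | None = None  # SyntheticSpec keyword arguments
    outdir: str = "flipscan_out"
    seed: int = 0

    # trimming / smoothing
    t_eq: float = 0.0  # ns of equilibration to discard
    smooth_window: float = 100.0  # ns
    block: float = 1000.0  # ns

    # scrambling thresholds
    theta_low: float = 35.0  # degrees
    theta_high: float = 145.0
    pathway_radius: float = 4.7  # angstrom

    # groove
    tm4: tuple[int, int] = (327, 339)
    tm6: tuple[int, int] = (430, 452)
    groove_chains: tuple[str, ...] = ("A",)
    groove_open: float = 6.0  # angstrom
    ewma_alpha: float = 0.1
    thickness_gate: float = 14.0  # angstrom

    # surfaces / densities
    surface_grid: float = 1.0  # angstrom
    occupancy_min: float = 0.02
    density_grid: float = 0.5  # angstrom
    density_extents: tuple[float, float, float] = (100.0, 100.0, 150.0)

    # contacts
    contact_cutoff: float = 7.0  # angstrom
    gap_tolerance: float = 6.0  # ns
    contact_residues: tuple[int, ...] = ()

    # permeation / kinetics
    tube_radius: float = 8.0  # angstrom
    z_margin: float = 5.0  # angstrom
    fe_bin: float = 1.0  # angstrom
    lag_range: tuple[int, int] = (1, 10)  # frames for the MSD fit

    def validate(self) -> None:
        if not (0 < self.theta_low < 90 < self.theta_high < 180):
            raise ValueError("need 0 < theta_low < 90 < theta_high < 180")
        for key in (
            "smooth_window", "block", "pathway_radius", "groove_open",
            "thickness_gate", "surface_grid", "density_grid",
            "contact_cutoff", "tube_radius", "fe_bin",
        ):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if not 0 < self.ewma_alpha <= 1:
            raise ValueError("ewma_alpha must be in (0, 1]")
        if not 0 <= self.occupancy_min <= 1:
            raise ValueError("occupancy_min must be in [0, 1]")


PROVENANCE: dict[str, str] = {
    "t_eq": "equilibration discarded before any analysis (ns); 1000 for production 10 us runs",
    "smooth_window": "centered running-average window for orientation angles (ns)",
    "block": "block length for rate averaging (ns; 1 us blocks)",
    "theta_low": "lower hysteresis threshold on the smoothed orientation angle (deg); upper-leaflet lipids complete a flip below it",
    "theta_high": "upper hysteresis threshold (deg); lower-leaflet lipids complete a flip above it",
    "pathway_radius": "max headgroup distance from the maximum-density pathway for an in-groove event (angstrom)",
    "tm4": "TM4 residue range for the groove-width minimum distance",
    "tm6": "TM6 residue range for the groove-width minimum distance",
    "groove_open": "TM4-TM6 smoothed distance above which the groove counts as open (angstrom)",
    "ewma_alpha": "smoothing factor of the recursive EWMA on the groove width",
    "thickness_gate": "minimal membrane thickness below which scrambling is robust (angstrom)",
    "surface_grid": "leaflet-surface grid spacing (angstrom)",
    "occupancy_min": "minimum fraction of frames a surface cell must be occupied",
    "density_grid": "3D density grid spacing (angstrom)",
    "density_extents": "3D density grid extents around the groove center (angstrom)",
    "contact_cutoff": "protein-lipid contact distance cutoff, strict < (angstrom)",
    "gap_tolerance": "max gap merged into one dwell (ns)",
    "tube_radius": "pathway tube radius for permeation and transit kinetics (angstrom)",
    "z_margin": "zone padding beyond the leaflet surfaces for permeation (angstrom)",
    "fe_bin": "free-energy profile bin width along the pathway (angstrom)",
    "lag_range": "MSD lag window for the diffusion fit (frames)",
}


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = AnalysisConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, tuple) and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, tuple):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        return "{" + ", ".join(f"{k} = {_toml_value(x)}" for k, x in v.items()) + "}"
    return repr(v)


def echo_config(cfg: AnalysisConfig) -> str:
    """TOML text of the config with a provenance comment on every threshold.

    Re-parses to an equivalent config (round-trip safe)."""
    lines = ["# flipscan analysis configuration"]
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if v is None:
            continue
        note = PROVENANCE.get(f.name)
        if note:
            lines.append(f"# {note}")
        lines.append(f"{f.name} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def save_config(cfg: AnalysisConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(echo_config(cfg))
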