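"""Plain-text readers and writers for configs, fields, tracks, and results.

All formats are delimited text (CSV/TSV) or flat YAML so outputs remain
diffable and portable; round trips are lossless to float repr precision.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .fitting import DecaySeries, FitResult
from .kymo import Kymograph
from .model import (
    FieldState,
    FieldTrajectory,
    ProductionProfile,
    SimulationConfig,
    SpatialGrid,
    make_production_profile,
)
from .quantify import MARGIN_TRACK_ID, CellTrack
from .receptor import ReceptorParams

__all__ = [
    "read_config", "write_config",
    "read_receptor_params",
    "write_fields", "read_fields",
    "write_tracks", "read_tracks", "split_margin_track",
    "write_kymograph", "read_kymograph",
    "write_decay_series", "read_decay_series",
    "write_fit_result",
]

_CONFIG_KEYS = {
    "length_um", "n_cells", "D_c", "D_T", "tau_T", "alpha", "beta", "K_half",
    "production_kind", "production_amplitude", "influx_rate", "influx_window_min",
    "initial_cells", "initial_T", "duration_min", "dt_min", "save_every_min", "seed",
    "receptor",
}


def write_config(config: SimulationConfig, path, receptor: ReceptorParams | None = None) -> None:
    """Write a flat YAML config mirroring the simulation parameter names."""
    data = {
        "length_um": config.grid.length_um,
        "n_cells": config.grid.n_cells,
        "D_c": config.D_c,
        "D_T": config.D_T,
        "tau_T": config.tau_T,
        "alpha": config.alpha,
        "beta": config.beta,
        "K_half": config.K_half,
        "production_kind": config.T0_profile.kind,
        "production_amplitude": config.T0_profile.amplitude,
        "influx_rate": config.influx_rate,
        "influx_window_min": config.influx_window_min,
        "initial_cells": config.initial_cells,
        "initial_T": config.initial_T,
        "duration_min": config.duration_min,
        "dt_min": config.dt_min,
        "save_every_min": config.save_every_min,
        "seed": config.seed,
    }
    if receptor is not None:
        data["receptor"] = {
            "r_max": receptor.r_max, "rho_R": receptor.rho_R,
            "k_bind": receptor.k_bind,
            "overexpression_factor": receptor.overexpression_factor,
        }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    grid = SpatialGrid(length_um=data.get("length_um", 600.0),
                       n_cells=data.get("n_cells", 60))
    profile = make_production_profile(data.get("production_kind", "uniform"),
                                      data.get("production_amplitude", 1.0), grid)
    kwargs = {k: data[k] for k in (
        "D_c", "D_T", "tau_T", "alpha", "beta", "K_half", "influx_rate",
        "influx_window_min", "initial_cells", "initial_T", "duration_min",
        "dt_min", "save_every_min", "seed") if k in data}
    return SimulationConfig(grid=grid, T0_profile=profile, **kwargs)


def read_receptor_params(path) -> ReceptorParams | None:
    data = yaml.safe_load(Path(path).read_text()) or {}
    block = data.get("receptor")
    return None if block is None else ReceptorParams(**block)


# ---------------------------------------------------------------------------
# field trajectories
# ---------------------------------------------------------------------------

def write_fields(trajectory: FieldTrajectory, path) -> None:
    """One row per saved time: t_min, c at each bin center, T at each bin center."""
    grid = trajectory.grid
    cols = (["t_min"]
            + [f"c@{x:g}" for x in grid.positions]
            + [f"T@{x:g}" for x in grid.positions])
    rows = [np.concatenate([[s.t_min], s.c, s.T]) for s in trajectory.states]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# length_um={grid.length_um:g} n_cells={grid.n_cells} "
                 f"beta={trajectory.config.beta:g} D_c={trajectory.config.D_c:g}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fields(path) -> FieldTrajectory:
    """Rebuild a trajectory (with a minimal config carrying the grid, beta and
    D_c from the header) from :func:`write_fields` output."""
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    grid = SpatialGrid(length_um=float(meta["length_um"]), n_cells=int(meta["n_cells"]))
    times = df["t_min"].to_numpy()
    n = grid.n_cells
    cfg = SimulationConfig(grid=grid, beta=float(meta["beta"]), D_c=float(meta["D_c"]),
                           duration_min=float(times[-1]) if len(times) else 0.0,
                           save_every_min=float(times[1] - times[0]) if len(times) > 1 else 1.0)
    states = []
    for _, row in df.iterrows():
        arr = row.to_numpy()
        states.append(FieldState(t_min=float(arr[0]), c=arr[1:1 + n], T=arr[1 + n:1 + 2 * n]))
    return FieldTrajectory(grid=grid, config=cfg, states=tuple(states))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_tracks(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for i in range(len(tr.t_min)):
            rows.append({
                "track_id": tr.track_id,
                "frame": i,
                "t_min": tr.t_min[i],
                "x_um": tr.x_um[i] if tr.x_um is not None else np.nan,
                "y_um": tr.y_um[i],
                "contact_t_min": tr.contact_t_min if tr.contact_t_min is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        x = sub["x_um"].to_numpy()
        contact = sub["contact_t_min"].iloc[0] if "contact_t_min" in sub else np.nan
        tracks.append(CellTrack(
            track_id=str(tid),
            t_min=sub["t_min"].to_numpy(),
            y_um=sub["y_um"].to_numpy(),
            x_um=None if np.all(np.isnan(x)) else x,
            contact_t_min=None if pd.isna(contact) else float(contact),
        ))
    return tracks


def split_margin_track(tracks):
    """Split ``tracks`` into (cell tracks, margin track or None)."""
    margin = None
    cells = []
    for tr in tracks:
        if tr.track_id == MARGIN_TRACK_ID:
            margin = tr
        else:
            cells.append(tr)
    return cells, margin


# ---------------------------------------------------------------------------
# kymographs, decay series, fit results
# ---------------------------------------------------------------------------

def write_kymograph(kym: Kymograph, path) -> None:
    """Matrix text: first row time-bin centers (min), first column
    distance-bin centers (um), missing bins written as NA."""
    df = pd.DataFrame(kym.values, index=kym.dist_centers, columns=kym.time_centers)
    df.index.name = "dist_um"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_kymograph(path) -> Kymograph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dist_c = df.index.to_numpy(dtype=float)
    time_c = df.columns.to_numpy(dtype=float)

    def centers_to_edges(c):
        if len(c) > 1:
            w = c[1] - c[0]
        else:
            w = 2 * c[0] if c[0] > 0 else 1.0
        return np.concatenate([[c[0] - w / 2], c + w / 2])

    values = df.to_numpy(dtype=float)
    counts = np.where(np.isnan(values), 0.0, 1.0)
    return Kymograph(dist_edges=centers_to_edges(dist_c),
                     time_edges=centers_to_edges(time_c),
                     values=values, counts=counts)


def write_decay_series(series: DecaySeries, path) -> None:
    df = pd.DataFrame({"t_min": series.times_min, "value": series.values})
    if series.sigma is not None:
        df["sigma"] = series.sigma
    df.to_csv(path, index=False)


def read_decay_series(path) -> DecaySeries:
    df = pd.read_csv(path)
    sigma = df["sigma"].to_numpy() if "sigma" in df else None
    return DecaySeries(times_min=df["t_min"].to_numpy(),
                       values=df["value"].to_numpy(), sigma=sigma)


def write_fit_result(result: FitResult, path) -> None:
    lines = [f"estimate\t{result.estimate!r}",
             f"standard_error\t{result.standard_error!r}",
             f"residual_norm\t{result.residual_norm!r}"]
    for key, val in result.diagnostics.items():
        lines.append(f"{key}\t{val!r}")
    Path(path).write_text("\n".join(lines) + "\n")
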