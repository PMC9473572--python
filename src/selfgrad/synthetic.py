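"""Seeded generators for every input the analysis pipeline consumes.

Agent-based tracks are Euler--Maruyama samples of the Langevin dynamics

.. math:: dx = \\beta\\,\\partial_x T(x, t)\\,dt + \\sqrt{2 D_c}\\,dW

with the ligand field interpolated from a PDE run.  Because the agents do not
interact and the PDE advection term is linear in the cell density, the agent
position density obeys the same Fokker--Planck equation as the continuum
density ``c(x, t)``, so coarse-binned agent histograms converge to the PDE
profile -- the module's central consistency property, exercised in the tests.

Also provided: pure-diffusion (Toddler-null) tracks, constant-velocity margin
(epiboly) reference tracks, exponential decay series with multiplicative
noise, synthetic membrane/cytoplasm cell images, and point-source attraction
scenarios with a finite guidance range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .fitting import DecaySeries
from .quantify import MARGIN_TRACK_ID, CellTrack, LabeledCellImage

__all__ = [
    "AgentConfig",
    "sample_agent_tracks",
    "make_mutant_tracks",
    "make_margin_track",
    "make_decay_series",
    "make_cell_image",
    "make_source_attraction_tracks",
]


@dataclass(frozen=True)
class AgentConfig:
    """Sampling configuration for agent-based tracks.

    ``spawn`` is either ``"bolus"`` (all agents released at the margin at
    t = 0) or ``"influx"`` (release times uniform over the influx window,
    emulating continuous internalization at the margin).
    """

    n_agents: int = 200
    seed: int = 0
    dt_min: float = 0.5
    D_c: float = 35.0
    beta: float = 32.0
    spawn: str = "bolus"
    observation_noise_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ConfigurationError("need at least one agent")
        if self.dt_min <= 0:
            raise ConfigurationError("agent dt must be positive")
        if self.spawn not in ("bolus", "influx"):
            raise ConfigurationError("spawn must be 'bolus' or 'influx'")
        if self.D_c < 0 or self.observation_noise_um < 0:
            raise ConfigurationError("D_c and observation noise must be non-negative")


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    x = np.abs(x)
    return L - np.abs(L - x)


def _drift_profiles(trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-saved-state gradient profiles dT/dx (times, positions, G[k, i]),
    including the receptor sensing attenuation when present."""
    grid = trajectory.grid
    times = trajectory.times
    G = np.array([np.gradient(s.T, grid.dx_um) for s in trajectory.states])
    scales = getattr(trajectory, "sensing_scales", None)
    if callable(scales):
        G *= np.array(scales())
    return times, grid.positions, G


def sample_agent_tracks(fields, agent_config: AgentConfig) -> list[CellTrack]:
    """Sample agent tracks consistent with a simulated field trajectory.

    The drift is ``beta * dT/dx`` with the gradient interpolated linearly in
    space and time between saved states; boundaries reflect at the margin and
    the animal pole.  Optional Gaussian observation noise perturbs recorded
    (not dynamical) positions.  Deterministic given the seed.
    """
    ac = agent_config
    times, pos, G = _drift_profiles(fields)
    cfg = fields.config
    save_dt = float(times[1] - times[0]) if len(times) > 1 else cfg.save_every_min
    if ac.dt_min > save_dt + 1e-9:
        raise ConfigurationError("agent dt must not exceed the field save cadence")
    L = fields.grid.length_um
    dx = fields.grid.dx_um
    duration = float(times[-1])
    n_steps = int(round(duration / ac.dt_min))
    rng = np.random.default_rng(ac.seed)

    if ac.spawn == "bolus":
        spawn_step = np.zeros(ac.n_agents, dtype=int)
    else:
        window = min(cfg.influx_window_min, duration)
        spawn_step = np.floor(rng.uniform(0, window / ac.dt_min, ac.n_agents)).astype(int)
        spawn_step = np.clip(spawn_step, 0, n_steps - 1)
    x = rng.uniform(0.0, dx, ac.n_agents)

    record = np.full((n_steps + 1, ac.n_agents), np.nan)
    active0 = spawn_step == 0
    record[0, active0] = x[active0]
    sig = np.sqrt(2.0 * ac.D_c * ac.dt_min)
    for k in range(n_steps):
        t = k * ac.dt_min
        active = spawn_step <= k
        if active.any():
            j = min(int(np.searchsorted(times, t, side="right")) - 1, len(times) - 2)
            w = (t - times[j]) / (times[j + 1] - times[j])
            g = (1 - w) * np.interp(x[active], pos, G[j]) + w * np.interp(x[active], pos, G[j + 1])
            x[active] = x[active] + ac.beta * g * ac.dt_min
            if ac.D_c > 0:
                x[active] = x[active] + sig * rng.standard_normal(int(active.sum()))
            x[active] = _reflect(x[active], L)
        newly = spawn_step == k + 1
        record[k + 1, active | newly] = x[active | newly]

    if ac.observation_noise_um > 0:
        noise = rng.normal(0.0, ac.observation_noise_um, record.shape)
        record = record + np.where(np.isnan(record), 0.0, noise)

    t_grid = ac.dt_min * np.arange(n_steps + 1)
    tracks = []
    width = len(str(ac.n_agents))
    for i in range(ac.n_agents):
        valid = ~np.isnan(record[:, i])
        if valid.sum() < 2:
            continue
        tracks.append(CellTrack(track_id=f"agent_{i:0{width}d}",
                                t_min=t_grid[valid], y_um=record[valid, i]))
    return tracks


def make_mutant_tracks(agent_config: AgentConfig, duration_min: float = 300.0,
                       domain_length_um: float = 600.0) -> list[CellTrack]:
    """Pure-diffusion (Toddler-null) tracks: a margin bolus with beta forced to 0."""
    ac = agent_config
    rng = np.random.default_rng(ac.seed)
    n_steps = int(round(duration_min / ac.dt_min))
    x = rng.uniform(0.0, domain_length_um / 60.0, ac.n_agents)
    record = np.empty((n_steps + 1, ac.n_agents))
    record[0] = x
    sig = np.sqrt(2.0 * ac.D_c * ac.dt_min)
    for k in range(n_steps):
        if ac.D_c > 0:
            x = x + sig * rng.standard_normal(ac.n_agents)
        x = _reflect(x, domain_length_um)
        record[k + 1] = x
    t_grid = ac.dt_min * np.arange(n_steps + 1)
    width = len(str(ac.n_agents))
    return [CellTrack(track_id=f"mutant_{i:0{width}d}", t_min=t_grid, y_um=record[:, i])
            for i in range(ac.n_agents)]


def make_margin_track(speed_um_per_min: float, duration_min: float,
                      dt_min: float = 1.0, y0_um: float = 0.0) -> CellTrack:
    """Constant-velocity vegetal-ward margin (epiboly) reference track."""
    t = dt_min * np.arange(int(round(duration_min / dt_min)) + 1)
    return CellTrack(track_id=MARGIN_TRACK_ID, t_min=t, y_um=y0_um - speed_um_per_min * t)


def make_decay_series(A: float = 100.0, tau_min: float = 120.0, interval_min: float = 30.0,
                      n_points: int = 7, cv: float = 0.0, seed: int = 0) -> DecaySeries:
    """Exponential decay sampled at fixed intervals with multiplicative noise.

    Defaults emulate the reference protocol: sampling every 30 min for 3 h
    (7 points).  Noise is mean-one log-normal with coefficient of variation
    ``cv``; ``cv = 0`` gives the exact exponential.
    """
    if tau_min <= 0:
        raise ConfigurationError("tau must be positive")
    t = interval_min * np.arange(n_points)
    v = A * np.exp(-t / tau_min)
    if cv > 0:
        s = np.sqrt(np.log1p(cv * cv))
        rng = np.random.default_rng(seed)
        v = v * np.exp(rng.normal(0.0, s, n_points) - 0.5 * s * s)
    return DecaySeries(times_min=t, values=v)


def make_cell_image(radius_um: float = 8.0, band_um: float = 1.25, contrast: float = 3.0,
                    pixel_size_um: float = 0.25, noise_cv: float = 0.0,
                    seed: int = 0) -> LabeledCellImage:
    """Synthetic labeled cell: a disk with a brighter membrane band.

    Interior intensity is 1; the outer band of width ``band_um`` (defined by
    the same Euclidean-distance rule the ratio measurement uses) has
    intensity ``contrast``.  Multiplicative Gaussian noise of relative
    standard deviation ``noise_cv`` is added when requested.
    """
    if band_um >= radius_um:
        raise ConfigurationError("membrane band must be thinner than the cell radius")
    half = radius_um + 4 * pixel_size_um
    n = int(np.ceil(2 * half / pixel_size_um))
    idx = (np.arange(n) + 0.5) * pixel_size_um - half
    X, Y = np.meshgrid(idx, idx)
    mask = X**2 + Y**2 <= radius_um**2
    dist = ndimage.distance_transform_edt(mask, sampling=pixel_size_um)
    intensity = np.zeros((n, n))
    intensity[mask & (dist <= band_um)] = contrast
    intensity[dist > band_um] = 1.0
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_cv * rng.standard_normal((n, n)))
        intensity = np.clip(intensity, 0.0, None)
    return LabeledCellImage(intensity=intensity, full_mask=mask, pixel_size_um=pixel_size_um)


def make_source_attraction_tracks(source_position: tuple[float, float] = (0.0, 0.0),
                                  max_range_um: float = 100.0,
                                  agent_config: AgentConfig | None = None,
                                  duration_min: float = 120.0,
                                  start_distances_um=None,
                                  contact_radius_um: float = 2.0) -> list[CellTrack]:
    """Tracks of cells attracted toward a point ligand source of finite range.

    Agents within ``max_range_um`` of the source drift straight toward it at
    speed ``agent_config.beta`` (um/min) and stop on contact; beyond the
    range they diffuse freely.  Emulates transplantation assays in which
    directional migration is induced only within ~100 um of the source.
    """
    ac = agent_config or AgentConfig()
    rng = np.random.default_rng(ac.seed)
    sx, sy = source_position
    if start_distances_um is None:
        start_distances_um = np.linspace(40.0, 160.0, ac.n_agents)
    d0 = np.asarray(start_distances_um, dtype=float)
    n = len(d0)
    x = np.full(n, sx)
    y = sy - d0
    n_steps = int(round(duration_min / ac.dt_min))
    rec = np.empty((n_steps + 1, n, 2))
    rec[0] = np.column_stack([x, y])
    sig = np.sqrt(2.0 * ac.D_c * ac.dt_min)
    contact_t = np.full(n, np.nan)
    for k in range(n_steps):
        dxs, dys = sx - x, sy - y
        dist = np.hypot(dxs, dys)
        guided = (dist <= max_range_um) & (dist > contact_radius_um)
        stepv = np.minimum(ac.beta * ac.dt_min, np.maximum(dist - contact_radius_um, 0.0))
        x = x + np.where(guided, stepv * dxs / np.maximum(dist, 1e-12), 0.0)
        y = y + np.where(guided, stepv * dys / np.maximum(dist, 1e-12), 0.0)
        free = dist > contact_radius_um
        if ac.D_c > 0:
            x = x + np.where(free, sig * rng.standard_normal(n), 0.0)
            y = y + np.where(free, sig * rng.standard_normal(n), 0.0)
        newly = np.isnan(contact_t) & (np.hypot(sx - x, sy - y) <= contact_radius_um)
        contact_t[newly] = (k + 1) * ac.dt_min
        rec[k + 1] = np.column_stack([x, y])
    t_grid = ac.dt_min * np.arange(n_steps + 1)
    width = len(str(n))
    return [
        CellTrack(track_id=f"src_{i:0{width}d}", t_min=t_grid, y_um=rec[:, i, 1],
                  x_um=rec[:, i, 0],
                  contact_t_min=None if np.isnan(contact_t[i]) else float(contact_t[i]))
        for i in range(n)
    ]
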