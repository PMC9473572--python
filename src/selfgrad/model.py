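"""One-dimensional self-generated chemokine gradient model.

Mesodermal cells internalize at the blastoderm margin (``x = 0``) and migrate
toward the animal pole (``x = L``) along the animal--vegetal axis.  The model
couples the mesodermal line density ``c(x, t)`` (cells/um) to the concentration
``T(x, t)`` of the secreted ligand Toddler (arbitrary concentration units):

.. math::

    \\partial_t c = D_c \\partial_x^2 c
                    - \\partial_x\\big[\\beta\\,(\\partial_x T)\\, c\\big] + J(x, t)

    \\partial_t T = D_T \\partial_x^2 T + T_0(x) - T/\\tau_T
                    - \\alpha\\, c\\, \\frac{T}{T + K}

Cells perform a random walk (motility coefficient ``D_c``) and drift up the
local ligand gradient with speed ``beta * dT/dx``.  The ligand diffuses
(``D_T``), is produced with a configurable spatial profile ``T_0(x)``, decays
with time scale ``tau_T``, and is removed by a mesodermal sink whose per-cell
capacity saturates at ``alpha`` (Michaelis form with half-saturation ``K``),
so that each cell removes ligand at a near-constant rate when ligand is
plentiful.  Local removal at the margin, where cells accumulate, tilts an
initially flat ligand field into an animal-ward gradient that the same cells
then read -- the self-generated gradient.

Discretization: finite volumes on a uniform grid, forward Euler in time,
central differences for diffusion, first-order upwinding for the advective
flux, and reflecting (zero-flux) boundaries for both fields.  The time step
is checked against ``dt <= 0.5 * min(dx^2 / (2 max(D_c, D_T)), dx / max|v|)``
every step, which keeps both fields non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    ConsistencyError,
    DegenerateInputError,
    StabilityError,
)
from .kymo import Kymograph, bin_edges_covering

__all__ = [
    "SpatialGrid",
    "ProductionProfile",
    "SimulationConfig",
    "FieldState",
    "FieldTrajectory",
    "make_production_profile",
    "default_config",
    "mutant_config",
    "step",
    "simulate",
    "velocity_field",
    "front_position",
    "kymograph_from_fields",
    "propagation_length",
    "total_cells",
]

PRODUCTION_KINDS = ("uniform", "graded_margin", "graded_animal", "none")

#: Packaged wild-type calibration (see docs/methods.md).  Only the products
#: alpha*beta and beta*T0*tau_T carry physical meaning; with T0 = 1/min the
#: coupling product alpha*beta = 96 um^2 conc/(cell min^2)-equivalents puts
#: the wild-type front near 500 um at 300 min on the 600-um domain.
ALPHA_DEFAULT = 3.0
BETA_DEFAULT = 32.0
#: Random cell motility, um^2/min; calibrated so that the pure-diffusion
#: (Toddler-null) front at 300 min is about half the wild-type front.
DC_DEFAULT = 35.0
#: Margin influx, cells/min (600 internalized cells over a 300-min run).
INFLUX_DEFAULT = 2.0
#: Uptake half-saturation as a fraction of the uniform-production steady
#: state T0*tau_T: small, so the per-cell removal capacity stays constant
#: down to strongly depleted ligand levels.
KHALF_FRACTION = 0.01


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform finite-volume grid on the animal--vegetal axis.

    ``x = 0`` is the margin (where cells internalize), ``x = length_um`` the
    animal pole.  Bin centers sit at ``dx/2, 3 dx/2, ...``.
    """

    length_um: float = 600.0
    n_cells: int = 60

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ConfigurationError("grid needs at least 10 bins")
        if self.length_um <= 0:
            raise ConfigurationError("domain length must be positive")

    @property
    def dx_um(self) -> float:
        return self.length_um / self.n_cells

    @property
    def positions(self) -> np.ndarray:
        dx = self.dx_um
        return dx * (np.arange(self.n_cells) + 0.5)


@dataclass(frozen=True)
class ProductionProfile:
    """Spatial ligand production profile ``T_0(x)`` (concentration/min).

    Graded kinds are linear ramps that vanish at the far *boundary* (not the
    far bin center) and whose spatial mean equals ``amplitude``, so all kinds
    except ``none`` inject the same total amount of ligand.
    """

    kind: str
    amplitude: float
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0):
            raise ConfigurationError("production rates must be non-negative")


def make_production_profile(kind: str, amplitude: float, grid: SpatialGrid) -> ProductionProfile:
    """Build a production profile of the given ``kind`` on ``grid``.

    Parameters
    ----------
    kind : {"uniform", "graded_margin", "graded_animal", "none"}
        ``graded_margin`` decreases linearly from the margin toward the animal
        pole (zero at ``x = L``); ``graded_animal`` is the mirror ramp.
    amplitude : float
        Spatial mean production rate (concentration/min); ignored for ``none``.
    """
    if kind not in PRODUCTION_KINDS:
        raise ConfigurationError(f"unknown production kind {kind!r}; expected one of {PRODUCTION_KINDS}")
    if amplitude < 0:
        raise ConfigurationError("amplitude must be non-negative")
    x = grid.positions
    L = grid.length_um
    if kind == "none":
        values = np.zeros_like(x)
    elif kind == "uniform":
        values = np.full_like(x, amplitude)
    elif kind == "graded_margin":
        values = 2.0 * amplitude * (1.0 - x / L)
    else:  # graded_animal
        values = 2.0 * amplitude * (x / L)
    return ProductionProfile(kind=kind, amplitude=float(amplitude), values=values)


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters and numerical settings for one model run.

    Units: lengths um, times min, cell density cells/um, ligand concentration
    arbitrary ("concentration") units.  Only the products ``alpha*beta`` and
    ``beta*T0*tau_T`` are physically meaningful; ``beta`` is gauge-fixed to 1
    by default (concentration-normalized units).

    ``initial_cells`` places a bolus of that many cells in the margin bin at
    ``t = 0`` (used by cohort/directionality experiments in which the influx
    is switched off).
    """

    grid: SpatialGrid = field(default_factory=SpatialGrid)
    D_c: float = DC_DEFAULT
    D_T: float = 3.0e3
    tau_T: float = 120.0
    alpha: float = ALPHA_DEFAULT
    beta: float = BETA_DEFAULT
    K_half: float | None = None
    T0_profile: ProductionProfile | None = None
    influx_rate: float = INFLUX_DEFAULT
    influx_window_min: float | None = None
    initial_cells: float = 0.0
    initial_T: str = "equilibrium"
    duration_min: float = 300.0
    dt_min: float | None = None
    save_every_min: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_c", "D_T", "alpha", "beta", "influx_rate", "initial_cells", "duration_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.tau_T <= 0:
            raise ConfigurationError("tau_T must be positive")
        if self.T0_profile is None:
            object.__setattr__(self, "T0_profile", make_production_profile("uniform", 1.0, self.grid))
        if len(self.T0_profile.values) != self.grid.n_cells:
            raise ConfigurationError("production profile does not match the grid")
        if self.K_half is None:
            # Uptake half-saturation: a small fraction of the uniform-
            # production steady state, i.e. saturated (constant per-cell
            # capacity) over nearly the whole ligand range while keeping the
            # sink smooth and positivity-preserving near T = 0.
            amp = self.T0_profile.amplitude if self.T0_profile.kind != "none" else 0.0
            if amp <= 0:
                amp = 1.0
            object.__setattr__(self, "K_half", KHALF_FRACTION * amp * self.tau_T)
        if self.K_half <= 0:
            raise ConfigurationError("K_half must be positive")
        if self.influx_window_min is None:
            object.__setattr__(self, "influx_window_min", self.duration_min)
        if self.initial_T not in ("equilibrium", "zero"):
            raise ConfigurationError("initial_T must be 'equilibrium' or 'zero'")

    # -- convenience -------------------------------------------------------
    def with_coupling(self, coupling: float) -> "SimulationConfig":
        """Return a copy whose coupling product alpha*beta equals ``coupling``.

        The sensing strength beta is adjusted at fixed uptake rate alpha:
        this is the direction in which the front position responds
        monotonically, and it matches the interpretation of the fitted
        parameter as the strength of self-generated directionality.
        """
        if self.alpha <= 0:
            raise ConfigurationError("cannot set coupling with alpha = 0")
        return replace(self, beta=coupling / self.alpha)

    @property
    def coupling(self) -> float:
        return self.alpha * self.beta


def default_config(**overrides) -> SimulationConfig:
    """Packaged wild-type configuration (uniform production, calibrated coupling)."""
    return SimulationConfig(**overrides)


def mutant_config(**overrides) -> SimulationConfig:
    """Toddler-null configuration: no ligand production, pure random motility."""
    cfg = SimulationConfig(**overrides)
    prof = make_production_profile("none", 0.0, cfg.grid)
    return replace(cfg, T0_profile=prof, initial_T="zero")


@dataclass(frozen=True)
class FieldState:
    """Snapshot of the two fields at one time."""

    t_min: float
    c: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        T = np.asarray(self.T, dtype=float)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "T", T)
        if c.shape != T.shape:
            raise ConfigurationError("c and T must have the same length")
        if np.any(c < 0) or np.any(T < 0):
            raise ConsistencyError("negative field value in FieldState")


@dataclass(frozen=True)
class FieldTrajectory:
    """Time-ordered sequence of saved field states from one run."""

    grid: SpatialGrid
    config: SimulationConfig
    states: tuple

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t_min for s in self.states])

    @property
    def final(self) -> FieldState:
        return self.states[-1]


def total_cells(state: FieldState, grid: SpatialGrid) -> float:
    """Total cell number: integral of the line density over the domain."""
    return float(np.sum(state.c) * grid.dx_um)


# ---------------------------------------------------------------------------
# integration core
# ---------------------------------------------------------------------------

def _stability_dt(cfg: SimulationConfig) -> float:
    """Diffusive part of the time-step bound (advection is checked per step)."""
    dx = cfg.grid.dx_um
    dmax = max(cfg.D_c, cfg.D_T)
    if dmax == 0:
        return cfg.save_every_min
    return 0.5 * dx * dx / (2.0 * dmax)


def _choose_dt(cfg: SimulationConfig) -> float:
    dt = cfg.dt_min if cfg.dt_min is not None else 0.9 * _stability_dt(cfg)
    dt = min(dt, cfg.save_every_min, cfg.duration_min)
    # land exactly on save times
    n_sub = max(1, int(np.ceil(cfg.save_every_min / dt - 1e-12)))
    return cfg.save_every_min / n_sub


def _initial_fields(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.grid.n_cells
    c = np.zeros(n)
    if cfg.initial_cells > 0:
        c[0] = cfg.initial_cells / cfg.grid.dx_um
    if cfg.initial_T == "equilibrium":
        T = cfg.T0_profile.values * cfg.tau_T
    else:
        T = np.zeros(n)
    return c, T.astype(float).copy()


def _advance(c: np.ndarray, T: np.ndarray, cfg: SimulationConfig, dt: float,
             t: float, r_scale: np.ndarray | None = None) -> None:
    """Advance both fields in place by one step of size ``dt``.

    ``r_scale`` (receptor availability r/r_max per bin, or None) multiplies
    both the per-cell uptake rate alpha and the gradient sensitivity beta,
    implementing the dual scavenger/sensor role of a single receptor pool.
    """
    dx = cfg.grid.dx_um
    n = c.shape[0]

    # interface gradient of T and advective velocity (upwind flux form)
    gradT = (T[1:] - T[:-1]) / dx
    if r_scale is None:
        beta_face = cfg.beta
    else:
        beta_face = cfg.beta * 0.5 * (r_scale[1:] + r_scale[:-1])
    v = beta_face * gradT
    vmax = float(np.max(np.abs(v))) if n > 1 else 0.0
    if vmax > 0 and dt > 0.5 * dx / vmax:
        raise StabilityError(
            f"dt = {dt:g} min violates the advective CFL bound "
            f"0.5*dx/max|v| = {0.5 * dx / vmax:g} min (max|v| = {vmax:g} um/min)"
        )
    if dt > 0.5 * dx * dx / (2.0 * max(cfg.D_c, cfg.D_T, 1e-300)):
        raise StabilityError(
            f"dt = {dt:g} min violates the diffusive bound "
            f"0.5*dx^2/(2 max(D_c, D_T)) = {0.5 * dx * dx / (2 * max(cfg.D_c, cfg.D_T)):g} min"
        )

    flux = np.where(v > 0, v * c[:-1], v * c[1:])          # advective, upwind
    flux -= cfg.D_c * (c[1:] - c[:-1]) / dx                # diffusive
    c[0] -= dt / dx * flux[0]
    c[-1] += dt / dx * flux[-1]
    if n > 2:
        c[1:-1] += dt / dx * (flux[:-1] - flux[1:])

    # ligand: diffusion (flux form, reflecting), production, decay, sink
    fT = -cfg.D_T * (T[1:] - T[:-1]) / dx
    alpha_eff = cfg.alpha if r_scale is None else cfg.alpha * r_scale
    sink_rate = alpha_eff * c * T / (T + cfg.K_half)
    decay = 1.0 / cfg.tau_T
    # explicit sink stability: per-bin loss rate must stay below 1/dt
    if cfg.alpha > 0:
        loss_rate = decay + alpha_eff * c / (T + cfg.K_half)
        if dt * float(np.max(loss_rate)) > 1.0:
            raise StabilityError(
                "dt violates the sink/decay stability bound dt*(1/tau_T + alpha*c/(T+K)) <= 1")
    T += dt * (cfg.T0_profile.values - T * decay - sink_rate)
    T[0] -= dt / dx * fT[0]
    T[-1] += dt / dx * fT[-1]
    if n > 2:
        T[1:-1] += dt / dx * (fT[:-1] - fT[1:])

    # influx of cells at the margin
    if cfg.influx_rate > 0 and t < cfg.influx_window_min:
        c[0] += dt * cfg.influx_rate / dx

    for name, f in (("c", c), ("T", T)):
        fmin = f.min()
        if fmin < 0:
            tol = 1e-10 * max(1.0, float(np.max(np.abs(f))))
            if fmin < -tol:
                raise ConsistencyError(f"{name} went negative ({fmin:g}) beyond round-off tolerance")
            np.clip(f, 0.0, None, out=f)


def step(state: FieldState, config: SimulationConfig, grid: SpatialGrid | None = None) -> FieldState:
    """Advance a field state by one time step ``config.dt_min``.

    Raises :class:`StabilityError` if the step size violates the CFL bound and
    :class:`ConsistencyError` if a field would go negative beyond round-off.
    """
    if grid is not None and grid != config.grid:
        raise ConfigurationError("grid does not match config.grid")
    dt = config.dt_min if config.dt_min is not None else 0.9 * _stability_dt(config)
    c = state.c.copy()
    T = state.T.copy()
    _advance(c, T, config, dt, state.t_min)
    return FieldState(t_min=state.t_min + dt, c=c, T=T)


def simulate(config: SimulationConfig) -> FieldTrajectory:
    """Integrate the coupled PDEs from ``t = 0`` to ``config.duration_min``.

    States are saved every ``save_every_min`` minutes (including t=0 and the
    final time).  Total cell number changes only through the margin influx.
    """
    cfg = config
    dt = _choose_dt(cfg)
    c, T = _initial_fields(cfg)
    states = [FieldState(0.0, c.copy(), T.copy())]
    n_saves = int(round(cfg.duration_min / cfg.save_every_min))
    n_sub = int(round(cfg.save_every_min / dt))
    t = 0.0
    for k in range(n_saves):
        for _ in range(n_sub):
            _advance(c, T, cfg, dt, t)
            t += dt
        t = (k + 1) * cfg.save_every_min  # suppress drift
        states.append(FieldState(t, c.copy(), T.copy()))
    return FieldTrajectory(grid=cfg.grid, config=cfg, states=tuple(states))


def velocity_field(state: FieldState, config: SimulationConfig,
                   r_scale: np.ndarray | None = None) -> np.ndarray:
    """Advective (chemotactic) velocity ``v(x) = beta * dT/dx`` at bin centers.

    Central differences in the interior, one-sided at the boundaries.  With
    the receptor extension, ``r_scale = r/r_max`` attenuates the sensitivity.
    """
    T = state.T
    v = np.gradient(T, config.grid.dx_um)
    beta = config.beta if r_scale is None else config.beta * r_scale
    return beta * v


def front_position(state: FieldState, grid: SpatialGrid, quantile: float = 0.95) -> float:
    """Quantile-based position of the mesodermal migration front, in um.

    Treats the density as piecewise constant per bin and returns the position
    at which the cumulative cell fraction counted from the margin first
    reaches ``quantile`` (linear interpolation inside the bin).
    """
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must lie in (0, 1)")
    mass = state.c * grid.dx_um
    total = mass.sum()
    if total <= 0:
        raise DegenerateInputError("front position undefined: zero total cell mass")
    cum = np.concatenate([[0.0], np.cumsum(mass)]) / total
    target = quantile
    i = int(np.searchsorted(cum, target, side="left")) - 1
    i = min(max(i, 0), grid.n_cells - 1)
    left_edge = i * grid.dx_um
    frac_in_bin = (target - cum[i]) / max(cum[i + 1] - cum[i], 1e-300)
    return float(left_edge + frac_in_bin * grid.dx_um)


def propagation_length(D_T: float, tau_T: float) -> float:
    """Ligand propagation length scale ``sqrt(D_T * tau_T)`` in um.

    With the packaged defaults (D_T = 3e3 um^2/min, tau_T = 120 min) this is
    600 um, the size of the embryo: ligand produced anywhere can reach the
    whole domain before decaying, which is what makes the sink location (the
    cells) rather than the source location set the gradient direction.
    """
    if D_T < 0 or tau_T < 0:
        raise ValueError("D_T and tau_T must be non-negative")
    return float(np.sqrt(D_T * tau_T))


def kymograph_from_fields(trajectory: FieldTrajectory, bin_um: float = 25.0,
                          bin_min: float = 10.0, normalize: bool = False,
                          include_diffusive_drift: bool = True) -> Kymograph:
    """Density-weighted mean animal-ward cell velocity in (distance, time) bins.

    The mean velocity of the cells in a bin is the flux velocity of the
    density field, ``u = beta dT/dx - D_c (dc/dx)/c``: the chemotactic drift
    plus the mean motion contributed by random motility down the density
    gradient.  This is the quantity a tracked cell population reports -- a
    purely diffusing population spreading from the margin still shows a
    positive early velocity that decays in time.  Set
    ``include_diffusive_drift=False`` for the advective (guidance) component
    alone.  Bins that contain no cells are missing (NaN); ``normalize=True``
    rescales by the maximum absolute entry.
    """
    if bin_um <= 0 or bin_min <= 0:
        raise ConfigurationError("kymograph bin sizes must be positive")
    if len(trajectory.states) < 2:
        raise ConfigurationError("need at least two saved states")
    grid = trajectory.grid
    cfg = trajectory.config
    times = trajectory.times
    dist_edges = bin_edges_covering(0.0, grid.length_um, bin_um)
    time_edges = bin_edges_covering(0.0, times[-1], bin_min)
    nd, nt = len(dist_edges) - 1, len(time_edges) - 1
    wsum = np.zeros((nd, nt))
    vsum = np.zeros((nd, nt))
    d_idx = np.clip(np.digitize(grid.positions, dist_edges) - 1, 0, nd - 1)
    for state in trajectory.states:
        t_idx = min(int(np.digitize(state.t_min, time_edges)) - 1, nt - 1)
        t_idx = max(t_idx, 0)
        v = velocity_field(state, cfg)
        if include_diffusive_drift and cfg.D_c > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                drift = -cfg.D_c * np.gradient(state.c, grid.dx_um) / state.c
            v = v + np.where(state.c > 0, np.nan_to_num(drift, nan=0.0, posinf=0.0,
                                                        neginf=0.0), 0.0)
        w = state.c * grid.dx_um
        np.add.at(wsum[:, t_idx], d_idx, w)
        np.add.at(vsum[:, t_idx], d_idx, w * v)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(wsum > 1e-9, vsum / np.maximum(wsum, 1e-300), np.nan)
    kym = Kymograph(dist_edges=dist_edges, time_edges=time_edges, values=values, counts=wsum)
    return kym.normalize() if normalize else kym
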