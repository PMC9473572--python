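"""Core PDE model: grids, production profiles, stepping, fronts, kymographs."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st

import selfgrad as sg
from selfgrad.errors import ConfigurationError, DegenerateInputError, StabilityError
from selfgrad.model import (
    _choose_dt,
    kymograph_from_fields,
    make_production_profile,
    total_cells,
)


# ---------------------------------------------------------------------------
# grid and production profiles
# ---------------------------------------------------------------------------

def test_grid_geometry():
    grid = sg.SpatialGrid(length_um=600.0, n_cells=60)
    assert grid.dx_um == 10.0
    assert grid.positions[0] == pytest.approx(5.0)
    assert grid.positions[-1] == pytest.approx(595.0)
    assert np.all(np.diff(grid.positions) > 0)


def test_grid_rejects_too_few_bins():
    with pytest.raises(ConfigurationError):
        sg.SpatialGrid(length_um=600.0, n_cells=5)


@pytest.mark.parametrize("kind, expected", [
    # linear ramps vanish at the far boundary and average to the amplitude:
    # on 10 bins of a 100-um domain the margin ramp runs 1.9, 1.7, ..., 0.1
    ("uniform", np.ones(10)),
    ("none", np.zeros(10)),
    ("graded_margin", np.linspace(1.9, 0.1, 10)),
    ("graded_animal", np.linspace(0.1, 1.9, 10)),
])
def test_production_profile_values(kind, expected):
    grid = sg.SpatialGrid(length_um=100.0, n_cells=10)
    prof = make_production_profile(kind, 1.0, grid)
    assert prof.values == pytest.approx(expected)
    if kind != "none":
        assert np.mean(prof.values) == pytest.approx(1.0)
    if kind == "graded_margin":
        assert np.all(np.diff(prof.values) < 0)
    if kind == "graded_animal":
        assert np.all(np.diff(prof.values) > 0)


def test_production_profile_unknown_kind():
    with pytest.raises(ConfigurationError):
        make_production_profile("sideways", 1.0, sg.SpatialGrid())


@given(kind=st.sampled_from(["uniform", "graded_margin", "graded_animal"]),
       amplitude=st.floats(0.01, 100.0),
       n=st.integers(10, 200))
def test_production_profile_mean_and_positivity(kind, amplitude, n):
    grid = sg.SpatialGrid(length_um=600.0, n_cells=n)
    prof = make_production_profile(kind, amplitude, grid)
    assert np.all(prof.values >= 0)
    assert np.mean(prof.values) == pytest.approx(amplitude, rel=1e-9)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def _quiet_config(**kw):
    grid = sg.SpatialGrid(600.0, 60)
    prof = make_production_profile(kw.pop("production", "none"),
                                   kw.pop("amplitude", 0.0), grid)
    defaults = dict(grid=grid, D_c=0.0, D_T=100.0, alpha=0.0, beta=0.0,
                    influx_rate=0.0, T0_profile=prof, initial_T="zero",
                    dt_min=0.1, K_half=1.0)
    defaults.update(kw)
    return sg.SimulationConfig(**defaults)


def test_step_null_dynamics_is_identity():
    cfg = _quiet_config()
    state = sg.FieldState(0.0, np.zeros(60), np.zeros(60))
    out = sg.step(state, cfg)
    assert out.c == pytest.approx(state.c)
    assert out.T == pytest.approx(state.T)


def test_step_holds_analytic_fixed_point():
    cfg = _quiet_config(production="uniform", amplitude=1.0, tau_T=120.0)
    state = sg.FieldState(0.0, np.zeros(60), np.full(60, 120.0))
    out = sg.step(state, cfg)
    assert out.T == pytest.approx(state.T)


def test_step_forward_euler_production_from_zero():
    cfg = _quiet_config(production="uniform", amplitude=1.0, tau_T=120.0)
    state = sg.FieldState(0.0, np.zeros(60), np.zeros(60))
    out = sg.step(state, cfg)
    assert out.T == pytest.approx(np.full(60, 0.1))


def test_step_rejects_unstable_dt():
    cfg = _quiet_config(D_T=3000.0, dt_min=1.0)
    state = sg.FieldState(0.0, np.zeros(60), np.zeros(60))
    with pytest.raises(StabilityError):
        sg.step(state, cfg)


# ---------------------------------------------------------------------------
# simulate: conservation, positivity, steady states
# ---------------------------------------------------------------------------

def test_influx_only_accumulates_at_margin():
    cfg = _quiet_config(D_T=0.0, influx_rate=1.0, dt_min=None,
                        duration_min=300.0, save_every_min=5.0)
    traj = sg.simulate(cfg)
    final = traj.final
    assert total_cells(final, traj.grid) == pytest.approx(300.0, rel=1e-12)
    assert final.c[1:] == pytest.approx(np.zeros(59))


def test_mass_conserved_without_influx():
    cfg = replace(sg.default_config(), influx_rate=0.0, initial_cells=100.0,
                  duration_min=60.0)
    traj = sg.simulate(cfg)
    masses = np.array([total_cells(s, traj.grid) for s in traj.states])
    assert np.all(np.abs(masses / 100.0 - 1.0) < 1e-8)


def test_fields_stay_nonnegative(wt_trajectory):
    for s in wt_trajectory.states:
        assert s.c.min() >= 0
        assert s.T.min() >= 0


def test_uniform_production_converges_to_equilibrium():
    cfg = _quiet_config(production="uniform", amplitude=1.0, tau_T=120.0,
                        D_T=3000.0, dt_min=None, duration_min=600.0,
                        save_every_min=10.0)
    traj = sg.simulate(cfg)
    assert traj.final.T == pytest.approx(np.full(60, 120.0), rel=0.01)


def test_wildtype_gradient_points_to_animal_pole(wt_trajectory):
    final = wt_trajectory.final
    assert final.T[0] < final.T[-1]


def test_front_advances_with_stronger_coupling():
    base = sg.default_config(grid=sg.SpatialGrid(600.0, 40), duration_min=150.0)
    lo = sg.front_position(sg.simulate(base).final, base.grid)
    hi_cfg = base.with_coupling(2 * base.coupling)
    hi = sg.front_position(sg.simulate(hi_cfg).final, base.grid)
    assert hi >= lo


def test_grid_convergence_of_front_position(wt_trajectory):
    """Halving dx (dt follows the CFL bound automatically) moves the
    300-min front by less than 2%."""
    coarse = sg.front_position(wt_trajectory.final, wt_trajectory.grid)
    fine_cfg = sg.default_config(grid=sg.SpatialGrid(600.0, 120))
    fine = sg.front_position(sg.simulate(fine_cfg).final, fine_cfg.grid)
    assert abs(fine - coarse) / coarse < 0.02


# ---------------------------------------------------------------------------
# velocity field and front position
# ---------------------------------------------------------------------------

def test_velocity_field_linear_gradient():
    grid = sg.SpatialGrid(600.0, 60)
    cfg = sg.SimulationConfig(grid=grid, beta=50.0)
    state = sg.FieldState(0.0, np.zeros(60), 0.02 * grid.positions)
    v = sg.velocity_field(state, cfg)
    assert v == pytest.approx(np.full(60, 1.0))


@pytest.mark.parametrize("beta, T", [
    (0.0, "linear"),
    (50.0, "constant"),
])
def test_velocity_field_vanishes(beta, T):
    grid = sg.SpatialGrid(600.0, 60)
    cfg = sg.SimulationConfig(grid=grid, beta=beta)
    vals = 0.02 * grid.positions if T == "linear" else np.full(60, 7.0)
    v = sg.velocity_field(sg.FieldState(0.0, np.zeros(60), vals), cfg)
    assert v == pytest.approx(np.zeros(60))


def test_front_position_uniform_density():
    grid = sg.SpatialGrid(600.0, 120)  # dx = 5
    c = np.where(grid.positions < 100.0, 1.0, 0.0)
    state = sg.FieldState(0.0, c, np.zeros(120))
    assert sg.front_position(state, grid, 0.95) == pytest.approx(95.0)


def test_front_position_single_bin_median():
    grid = sg.SpatialGrid(600.0, 120)
    c = np.zeros(120)
    c[0] = 3.0
    state = sg.FieldState(0.0, c, np.zeros(120))
    assert sg.front_position(state, grid, 0.5) == pytest.approx(2.5)


def test_front_position_triangular_density():
    grid = sg.SpatialGrid(600.0, 600)  # dx = 1
    c = np.where(grid.positions < 100.0, grid.positions, 0.0)
    state = sg.FieldState(0.0, c, np.zeros(600))
    assert sg.front_position(state, grid, 0.5) == pytest.approx(100 / np.sqrt(2), rel=0.01)


def test_front_position_empty_density_errors():
    grid = sg.SpatialGrid(600.0, 60)
    state = sg.FieldState(0.0, np.zeros(60), np.zeros(60))
    with pytest.raises(DegenerateInputError):
        sg.front_position(state, grid)


@given(q=st.floats(0.05, 0.95))
def test_front_position_monotone_in_quantile(q):
    grid = sg.SpatialGrid(600.0, 60)
    rng = np.random.default_rng(7)
    c = rng.uniform(0.1, 1.0, 60)
    state = sg.FieldState(0.0, c, np.zeros(60))
    lo = sg.front_position(state, grid, q / 2)
    hi = sg.front_position(state, grid, q)
    assert 0 <= lo <= hi <= 600.0


# ---------------------------------------------------------------------------
# propagation length
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("D_T, tau, expected", [
    (3000.0, 120.0, 600.0),
    (1.0, 1.0, 1.0),
    (4.0, 9.0, 6.0),
])
def test_propagation_length(D_T, tau, expected):
    assert sg.propagation_length(D_T, tau) == pytest.approx(expected)


def test_propagation_length_rejects_negative():
    with pytest.raises(ValueError):
        sg.propagation_length(-1.0, 10.0)


# ---------------------------------------------------------------------------
# field kymographs
# ---------------------------------------------------------------------------

def _frozen_trajectory(T, c, n_states=4, beta=1.0, D_c=0.0):
    grid = sg.SpatialGrid(600.0, 60)
    cfg = sg.SimulationConfig(grid=grid, beta=beta, D_c=D_c, save_every_min=10.0,
                              duration_min=10.0 * (n_states - 1))
    states = tuple(sg.FieldState(10.0 * k, c, T) for k in range(n_states))
    return sg.FieldTrajectory(grid=grid, config=cfg, states=states)


def test_kymograph_advective_only_zero_without_sensing():
    grid = sg.SpatialGrid(600.0, 60)
    traj = _frozen_trajectory(T=0.02 * grid.positions, c=np.ones(60), beta=0.0)
    kym = kymograph_from_fields(traj, 50, 10, include_diffusive_drift=False)
    assert np.nanmax(np.abs(kym.values)) == pytest.approx(0.0)


def test_kymograph_uniform_velocity_frozen_linear_field():
    grid = sg.SpatialGrid(600.0, 60)
    traj = _frozen_trajectory(T=0.02 * grid.positions, c=np.ones(60), beta=50.0)
    kym = kymograph_from_fields(traj, 50, 10)
    vals = kym.values[~kym.missing]
    assert vals == pytest.approx(np.full(vals.size, 1.0))


def test_kymograph_rejects_bad_bins(wt_trajectory):
    with pytest.raises(ConfigurationError):
        kymograph_from_fields(wt_trajectory, bin_um=-5.0)


def test_kymograph_normalization(wt_trajectory):
    kym = kymograph_from_fields(wt_trajectory, 50, 30, normalize=True)
    assert np.nanmax(np.abs(kym.values)) == pytest.approx(1.0)


def test_auto_dt_respects_cfl():
    cfg = sg.default_config()
    dt = _choose_dt(cfg)
    bound = 0.5 * cfg.grid.dx_um**2 / (2 * max(cfg.D_c, cfg.D_T))
    assert dt <= bound
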