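"""Parameter estimation: ligand decay time scale and guidance strength.

Two fits anchor the model to data.  The ligand degradation time scale
``tau_T`` comes from a single-exponential fit to protein abundance measured
at fixed intervals after an injection pulse (every 30 min for 3 h in the
reference experiment, giving tau_T of about 2 hours).  The strength of
self-generated directionality -- the product ``alpha * beta`` of per-cell
ligand consumption and gradient-to-speed coupling -- is the model's single
free parameter and is fitted by matching predicted to observed velocity
kymographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DegenerateInputError
from .kymo import Kymograph
from .model import SimulationConfig, kymograph_from_fields, simulate

__all__ = ["DecaySeries", "FitResult", "fit_exponential_decay", "fit_coupling"]


@dataclass(frozen=True)
class DecaySeries:
    """Time-stamped protein abundance measurements for exponential fitting."""

    times_min: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if len(t) < 3 or v.shape != t.shape:
            raise ConfigurationError("a decay series needs >= 3 (t, value) points")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if np.any(v <= 0):
            raise DegenerateInputError("abundances must be positive for a log-domain fit")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != t.shape or np.any(s <= 0):
                raise ConfigurationError("sigma must be positive and match times")


@dataclass(frozen=True)
class FitResult:
    """Point estimate with uncertainty and fit diagnostics."""

    estimate: float
    standard_error: float
    residual_norm: float
    diagnostics: dict = field(default_factory=dict)


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Wald--Wolfowitz runs test on residual signs (normal approximation);
    small p flags systematic lack of fit (e.g. multi-exponential decay)."""
    signs = residuals > 0
    n1 = int(signs.sum())
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 1 + 2 * n1 * n2 / (n1 + n2)
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def fit_exponential_decay(series: DecaySeries) -> FitResult:
    """Fit ``A * exp(-t / tau)``; returns tau (min) with its standard error.

    A weighted least-squares line fit in the log domain (convex, global)
    provides the start point; a nonlinear refinement on the original scale
    follows.  Diagnostics: fitted ``amplitude``, a runs-test p-value on the
    log-residuals, and ``single_exponential_ok``.
    """
    t, v = series.times_min, series.values
    logv = np.log(v)
    w = None if series.sigma is None else (v / series.sigma) ** 2  # delta method
    W = np.ones_like(t) if w is None else w
    # weighted linear fit log v = b0 + b1 t
    X = np.column_stack([np.ones_like(t), t])
    WX = X * W[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ logv, rcond=None)
    b0, b1 = beta
    if b1 >= -1e-12:
        raise DegenerateInputError("series does not decay (non-negative log-slope)")
    tau0, A0 = -1.0 / b1, float(np.exp(b0))

    def model(tt, A, tau):
        return A * np.exp(-tt / tau)

    sigma = series.sigma
    try:
        popt, pcov = optimize.curve_fit(model, t, v, p0=[A0, tau0], sigma=sigma,
                                        absolute_sigma=sigma is not None, maxfev=10000)
        A_hat, tau_hat = popt
        tau_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    except RuntimeError:
        A_hat, tau_hat, tau_se = A0, tau0, float("nan")
    if tau_hat <= 0:
        raise DegenerateInputError("refined decay time is non-positive")
    resid = v - model(t, A_hat, tau_hat)
    log_resid = logv - (np.log(A_hat) - t / tau_hat)
    p_runs = _runs_test_pvalue(log_resid)
    return FitResult(
        estimate=float(tau_hat),
        standard_error=tau_se,
        residual_norm=float(np.linalg.norm(resid)),
        diagnostics={"amplitude": float(A_hat), "runs_pvalue": p_runs,
                     "single_exponential_ok": p_runs > 0.01},
    )


def fit_coupling(observed: Kymograph, base_config: SimulationConfig,
                 decades: float = 1.25, xatol: float = 1e-4,
                 min_count: float = 0.0, n_scan: int = 9) -> FitResult:
    """Fit the guidance-strength product ``alpha * beta`` to a kymograph.

    Minimizes the sum of squared differences between the observed kymograph
    and the model prediction over the shared non-missing bins, comparing
    normalized velocities (so the fit is invariant to uniform rescaling of
    the observation).  The search is a bracketed scalar minimization over
    ``log10(alpha * beta)`` spanning ``decades`` decades either side of the
    configured default.

    For kymographs measured from finite track samples, set ``min_count``
    (e.g. 10) to exclude sparsely populated bins.  Bins are weighted by
    their sample counts (cell mass for field-derived kymographs).  If the
    observed kymograph is in physical units (not normalized), velocities are
    compared directly; if it is normalized, the unknown velocity scale is
    profiled out analytically, which makes the fit exactly invariant to
    uniform rescaling of the observed values.
    """
    g0 = base_config.coupling
    if g0 <= 0:
        raise ConfigurationError("base config must have a positive coupling to bracket the search")
    bin_um = float(np.diff(observed.dist_edges)[0])
    bin_min = float(np.diff(observed.time_edges)[0])
    if min_count > 0:
        masked = np.where(observed.counts >= min_count, observed.values, np.nan)
        observed = Kymograph(dist_edges=observed.dist_edges, time_edges=observed.time_edges,
                             values=masked, counts=observed.counts,
                             normalized=observed.normalized)
    obs = observed

    evals: dict[float, float] = {}

    def objective(log_g: float) -> float:
        if log_g in evals:
            return evals[log_g]
        cfg = base_config.with_coupling(10.0 ** log_g)
        sim = kymograph_from_fields(simulate(cfg), bin_um=bin_um, bin_min=bin_min,
                                    normalize=obs.normalized)
        shared = ~obs.missing & ~sim.missing
        if not shared.any():
            raise DegenerateInputError("no overlapping non-missing kymograph bins")
        w = obs.counts[shared]
        wsum = float(w.sum())
        if wsum <= 0:
            w = np.ones_like(w)
            wsum = float(w.sum())
        o = obs.values[shared]
        m = sim.values[shared]
        if obs.normalized:
            denom = float(np.sum(w * o * o))
            scale = float(np.sum(w * o * m)) / denom if denom > 0 else 0.0
        else:
            scale = 1.0
        sse = float(np.sum(w * (scale * o - m) ** 2) / wsum)
        evals[log_g] = sse
        return sse

    lo, hi = np.log10(g0) - decades, np.log10(g0) + decades
    # coarse log-grid scan brackets the global minimum before refinement,
    # guarding against shallow secondary basins at extreme couplings
    grid_pts = np.linspace(lo, hi, n_scan)
    grid_vals = [objective(float(p)) for p in grid_pts]
    k = int(np.argmin(grid_vals))
    blo = grid_pts[max(k - 1, 0)]
    bhi = grid_pts[min(k + 1, n_scan - 1)]
    res = optimize.minimize_scalar(objective, bounds=(float(blo), float(bhi)),
                                   method="bounded", options={"xatol": xatol})
    log_g_hat = float(res.x)
    if res.fun > grid_vals[k]:
        log_g_hat = float(grid_pts[k])
    at_bound = k in (0, n_scan - 1)
    return FitResult(
        estimate=float(10.0 ** log_g_hat),
        standard_error=float("nan"),
        residual_norm=float(np.sqrt(min(res.fun, grid_vals[k]))),
        diagnostics={"at_search_bound": bool(at_bound), "n_evaluations": len(evals),
                     "log10_bounds": (float(lo), float(hi))},
    )
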