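"""Stochastic integration of the thalamocortical model.

The exogenous drive P(t) is Gaussian white noise discretized by a
zero-order hold: one independent Normal(mu_r, phi_r) value per
integration step, held constant across the step.  The reference
integrator is classical fixed-step fourth-order Runge-Kutta on the
held-noise grid, which makes every run exactly reproducible from its
seed; an adaptive RK45 mode over the same held noise is available for
cross-checking the stepping scheme.

Repeats use statistically independent, individually seeded noise
streams (Philox counter-based generators keyed ``seed + repeat_index``)
so that any repeat can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError
from .model import ModelParameters, NeuralState, make_batch_rhs, output_potential

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "Drive",
    "make_drive",
    "integrate",
    "run_repeats",
    "run_grid",
]

logger = logging.getLogger(__name__)

#: Any state magnitude beyond this is treated as divergence (mV scale).
DEFAULT_BLOWUP_BOUND = 1e6
#: Steps between divergence checks in the batched integrator.
_CHECK_EVERY = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Time-stepping and repeat schedule.

    duration : total simulated time, s
    dt : integration / noise-hold step, s
    transient : initial span discarded before analysis, s
    n_repeats : number of independent noise realizations
    seed : base random seed (repeat ``i`` uses ``seed + i``)
    initial_state : starting state, default all zeros
    method : "rk4" (fixed-step reference) or "rk45" (adaptive, held noise)
    blowup_bound : divergence threshold, mV
    """

    duration: float = 30.0
    dt: float = 1e-3
    transient: float = 2.0
    n_repeats: int = 20
    seed: int = 0
    initial_state: Optional[NeuralState] = None
    method: str = "rk4"
    blowup_bound: float = DEFAULT_BLOWUP_BOUND

    def __post_init__(self):
        if not 0 < self.dt < self.duration:
            raise ConfigurationError(f"need 0 < dt < duration, got dt={self.dt}, duration={self.duration}")
        if not 0 <= self.transient < self.duration:
            raise ConfigurationError(f"need 0 <= transient < duration, got {self.transient}")
        if self.n_repeats < 1:
            raise ConfigurationError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.method not in ("rk4", "rk45"):
            raise ConfigurationError(f"method must be 'rk4' or 'rk45', got {self.method!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def fs(self) -> float:
        """Sampling rate of the output grid, Hz."""
        return 1.0 / self.dt

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def initial_array(self) -> np.ndarray:
        state = self.initial_state if self.initial_state is not None else NeuralState()
        state.validate()
        return state.to_array()


@dataclass
class SimulationResult:
    """Post-transient output traces of a repeated stochastic run."""

    time: np.ndarray          # post-transient time grid, s
    traces: np.ndarray        # (n_repeats, len(time)) output potential, mV
    mean_trace: np.ndarray    # pointwise mean across repeats, mV
    tau_i_used: float         # inhibitory time constant in effect, ms
    seeds: list               # per-repeat seeds actually used
    config: SimulationConfig
    params: ModelParameters


class Drive:
    """Piecewise-constant (zero-order-hold) realization of P(t).

    Callable: ``drive(t)`` returns the value held on the step
    containing ``t``.  The raw per-step samples are exposed as
    ``.samples`` for array-based integration.
    """

    def __init__(self, samples: np.ndarray, dt: float, seed_used: Optional[int] = None):
        self.samples = np.asarray(samples, dtype=float)
        self.dt = float(dt)
        self.seed_used = seed_used

    def __call__(self, t):
        idx = np.clip((np.asarray(t) / self.dt).astype(int), 0, len(self.samples) - 1)
        out = self.samples[idx]
        return float(out) if np.ndim(t) == 0 else out


def _repeat_seed(seed: int, repeat_index: int) -> int:
    return int(seed) + int(repeat_index)


def _noise_samples(n: int, mu_r: float, phi_r: float, seed: int, repeat_index: int) -> np.ndarray:
    if phi_r < 0:
        raise ConfigurationError(f"phi_r must be >= 0, got {phi_r}")
    key = _repeat_seed(seed, repeat_index)
    rng = np.random.Generator(np.random.Philox(key=key))
    if phi_r == 0:
        return np.full(n, float(mu_r))
    return rng.normal(mu_r, np.sqrt(phi_r), size=n)


def make_drive(config: SimulationConfig, mu_r: float, phi_r: float, repeat_index: int = 0) -> Drive:
    """Generate the seeded white-noise drive for one repeat.

    One i.i.d. Normal(mu_r, phi_r) draw per step of ``config.dt``,
    reproducible from ``(config.seed, repeat_index)``.
    """
    samples = _noise_samples(config.n_steps, mu_r, phi_r, config.seed, repeat_index)
    return Drive(samples, config.dt, seed_used=_repeat_seed(config.seed, repeat_index))


def _run_columns(params: ModelParameters, config: SimulationConfig, noise: np.ndarray,
                 tau_i_ms=None, C1=None, store_full: bool = False):
    """Integrate all noise columns at once; returns V trace (and states)."""
    rhs = make_batch_rhs(params, tau_i_ms=tau_i_ms, C1=C1)
    n_steps, m = noise.shape
    y0 = np.tile(config.initial_array().reshape(6, 1), (1, m))
    dt = config.dt
    bound = config.blowup_bound
    y = y0.copy()
    k1 = np.empty_like(y); k2 = np.empty_like(y)
    k3 = np.empty_like(y); k4 = np.empty_like(y)
    v = np.empty((n_steps + 1, m))
    v[0] = params.C3 * y[0] - params.C2 * y[4]
    full = np.empty((n_steps + 1, 6, m)) if store_full else None
    if store_full:
        full[0] = y
    half = dt / 2.0
    sixth = dt / 6.0
    for k in range(n_steps):
        p = noise[k]
        rhs(y, p, k1)
        rhs(y + half * k1, p, k2)
        rhs(y + half * k2, p, k3)
        rhs(y + dt * k3, p, k4)
        y = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        v[k + 1] = params.C3 * y[0] - params.C2 * y[4]
        if store_full:
            full[k + 1] = y
        if (k + 1) % _CHECK_EVERY == 0 or k == n_steps - 1:
            if not np.all(np.abs(y) < bound):
                t_fail = (k + 1) * dt
                raise IntegrationError(
                    f"state magnitude exceeded {bound:g} near t = {t_fail:.3f} s",
                    time=t_fail,
                )
    return v, full


def integrate(params: ModelParameters, config: SimulationConfig, drive):
    """Integrate a single trajectory under a given drive.

    Parameters
    ----------
    drive : callable
        ``t -> P(t)``; sampled at the left edge of each step (the
        zero-order-hold convention), so a :class:`Drive` built on a
        coarser grid is honoured exactly when integrating with a
        finer ``dt``.

    Returns
    -------
    (time, trajectory)
        ``time``: shape ``(n_steps + 1,)``; ``trajectory``: shape
        ``(n_steps + 1, 6)`` — full state on the uniform grid.

    Raises
    ------
    IntegrationError
        If any state magnitude exceeds ``config.blowup_bound``.
    """
    t = config.time_grid()
    held = np.asarray(drive(t[:-1]), dtype=float).reshape(-1, 1)
    if config.method == "rk45":
        rhs = make_batch_rhs(params)

        def f(ti, yi):
            out = np.empty((6, 1))
            rhs(yi.reshape(6, 1), np.atleast_1d(drive(ti)), out)
            return out[:, 0]

        sol = solve_ivp(f, (t[0], t[-1]), config.initial_array(), t_eval=t,
                        method="RK45", max_step=config.dt, rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise IntegrationError(f"RK45 integration failed: {sol.message}")
        traj = sol.y.T
        if not np.all(np.abs(traj) < config.blowup_bound):
            bad = np.argmax(np.any(np.abs(traj) >= config.blowup_bound, axis=1))
            raise IntegrationError("state diverged", time=t[bad])
        return t, traj
    _, full = _run_columns(params, config, held, store_full=True)
    return t, full[:, :, 0]


def run_repeats(params: ModelParameters, config: SimulationConfig) -> SimulationResult:
    """Run ``n_repeats`` independently seeded realizations.

    All repeats are integrated in one vectorized RK4 pass (column per
    repeat), which is arithmetically identical to integrating them one
    at a time.  The transient span is discarded from the returned
    traces; the pointwise mean across repeats is also provided.
    """
    return run_grid([params], config)[0]


def run_grid(param_points: Sequence[ModelParameters], config: SimulationConfig,
             ) -> list:
    """Integrate several parameter points, each with ``n_repeats`` noise
    realizations, in a single vectorized pass.

    Point ``j``, repeat ``i`` uses seed ``config.seed + j*n_repeats + i``,
    so a one-point grid reproduces :func:`run_repeats` exactly.
    Returns one :class:`SimulationResult` per point.
    """
    if len(param_points) == 0:
        raise ConfigurationError("param_points must be non-empty")
    if config.method == "rk45":
        return [_run_point_rk45(p, config, j * config.n_repeats)
                for j, p in enumerate(param_points)]
    n_pts = len(param_points)
    n_rep = config.n_repeats
    m = n_pts * n_rep
    n = config.n_steps
    base = param_points[0]
    tau_cols = np.repeat([p.tau_i for p in param_points], n_rep)
    c1_cols = np.repeat([p.C1 for p in param_points], n_rep)
    seeds = [[_repeat_seed(config.seed, j * n_rep + i) for i in range(n_rep)]
             for j in range(n_pts)]
    noise = np.empty((n, m))
    for j, p in enumerate(param_points):
        if p.trn_input != base.trn_input or p.H_e != base.H_e or p.H_i != base.H_i \
                or p.tau_e != base.tau_e or p.nu != base.nu or p.s0 != base.s0 \
                or p.e0 != base.e0 or p.C2 != base.C2 or p.C3 != base.C3:
            raise ConfigurationError(
                "run_grid varies only tau_i, C1 and the drive moments across points"
            )
        for i in range(n_rep):
            col = j * n_rep + i
            noise[:, col] = _noise_samples(n, p.mu_r, p.phi_r, config.seed, j * n_rep + i)
    logger.info("integrating %d columns (%d points x %d repeats), %d steps",
                m, n_pts, n_rep, n)
    v, _ = _run_columns(base, config, noise, tau_i_ms=tau_cols, C1=c1_cols)
    t = config.time_grid()
    keep = t >= config.transient
    results = []
    for j, p in enumerate(param_points):
        traces = v[keep][:, j * n_rep:(j + 1) * n_rep].T.copy()
        results.append(SimulationResult(
            time=t[keep].copy(), traces=traces, mean_trace=traces.mean(axis=0),
            tau_i_used=p.tau_i, seeds=seeds[j], config=config, params=p,
        ))
    return results


def _run_point_rk45(params: ModelParameters, config: SimulationConfig,
                    seed_offset: int) -> SimulationResult:
    t = config.time_grid()
    keep = t >= config.transient
    traces = []
    seeds = []
    for i in range(config.n_repeats):
        drive = Drive(
            _noise_samples(config.n_steps, params.mu_r, params.phi_r,
                           config.seed, seed_offset + i),
            config.dt, seed_used=_repeat_seed(config.seed, seed_offset + i))
        seeds.append(drive.seed_used)
        try:
            _, traj = integrate(params, config, drive)
        except IntegrationError as err:
            err.repeat_index = i
            raise
        traces.append(output_potential(traj, params)[keep])
    traces = np.asarray(traces)
    return SimulationResult(
        time=t[keep].copy(), traces=traces, mean_trace=traces.mean(axis=0),
        tau_i_used=params.tau_i, seeds=seeds, config=config, params=params,
    )
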