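"""Parameter-sweep drivers and reporting.

Three one-dimensional sweeps probe the spectral consequences of the
model's couplings:

* ``beta_a`` — amyloid load; raises the TRN inhibitory time constant
  through the calibrated sigmoid and is expected to lower the
  alpha-band peak power and dominant frequency (alpha slowing).
* ``C1`` — TCR->TRN excitatory gain, swept at fixed pathological load.
* ``mu_r`` — mean sensory drive, swept at fixed pathological load.

Each grid point runs the full repeat schedule; the per-repeat PSDs
are averaged and summarized over the alpha band.  All points of a
sweep are integrated in one vectorized pass, with seeds laid out so
that a single-point sweep is bit-identical to a direct
:func:`thalabeta.simulation.run_repeats` call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .abeta import AbetaMappingParameters, calibrate, tau_i_of_beta
from .errors import ConfigurationError
from .model import ModelParameters
from .simulation import SimulationConfig, run_grid
from .spectral import SpectralConfig, SpectralSummary, summarize_traces

__all__ = [
    "SweepSpec",
    "SweepResult",
    "sweep_beta",
    "sweep_c1",
    "sweep_mu",
    "run_sweep",
    "report",
    "DEFAULT_BETA_GRID",
    "DEFAULT_C1_GRID",
    "DEFAULT_MU_GRID",
]

logger = logging.getLogger(__name__)

#: Default amyloid grid: the clinical 1.4-5.0 range in steps of 0.2,
#: plus the spot values used for the time-series / PSD comparisons.
DEFAULT_BETA_GRID = tuple(sorted(set(np.round(np.arange(1.4, 5.01, 0.2), 10))
                                 | {0.001, 1.92, 2.10, 2.14, 3.00}))
DEFAULT_C1_GRID = tuple(float(x) for x in range(0, 101, 10))
DEFAULT_MU_GRID = tuple(float(x) for x in range(0, 101, 10))

_PARAMETERS = ("beta_a", "C1", "mu_r")


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep description.

    parameter : which knob to vary ("beta_a", "C1" or "mu_r")
    grid : strictly increasing values for that knob
    beta_a, c1, mu_r : fixed values for the knobs not swept
    seed : base seed for the repeat schedule
    out_prefix : path prefix for :func:`report` artifacts (optional)
    """

    parameter: str
    grid: Sequence[float]
    beta_a: float = 2.10
    c1: float = 35.0
    mu_r: float = 86.0
    seed: int = 0
    out_prefix: Optional[str] = None

    def __post_init__(self):
        if self.parameter not in _PARAMETERS:
            raise ConfigurationError(
                f"parameter must be one of {_PARAMETERS}, got {self.parameter!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise ConfigurationError("sweep grid must be non-empty")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ConfigurationError("sweep grid must be strictly increasing")
        if self.parameter == "mu_r":
            lo, hi = g[0], g[-1]
        else:
            lo = hi = self.mu_r
        if not (0 <= lo and hi <= 100):
            raise ConfigurationError(f"mu_r values must lie in [0, 100]")
        if self.c1 < 0 or (self.parameter == "C1" and g[0] < 0):
            raise ConfigurationError("C1 must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.grid, dtype=float)


@dataclass
class SweepResult:
    """Per-grid-point spectral summaries in tidy long format."""

    spec: SweepSpec
    table: pd.DataFrame            # one row per grid point
    summaries: list                # SpectralSummary per grid point
    tau_i_ms: np.ndarray           # effective inhibitory constant per point
    manifest: dict                 # every effective parameter and seed


def _point_parameters(spec: SweepSpec, params: ModelParameters,
                      mapping: AbetaMappingParameters):
    """ModelParameters for every grid point, with tau_i resolved."""
    points = []
    taus = []
    for value in spec.values:
        beta = value if spec.parameter == "beta_a" else spec.beta_a
        c1 = value if spec.parameter == "C1" else spec.c1
        mu = value if spec.parameter == "mu_r" else spec.mu_r
        tau = float(tau_i_of_beta(beta, mapping))
        points.append(params.with_(tau_i=tau, C1=float(c1), mu_r=float(mu)))
        taus.append(tau)
    return points, np.asarray(taus)


def run_sweep(spec: SweepSpec,
              params: Optional[ModelParameters] = None,
              mapping: Optional[AbetaMappingParameters] = None,
              sim_config: Optional[SimulationConfig] = None,
              spectral_config: Optional[SpectralConfig] = None) -> SweepResult:
    """Execute a sweep: simulate every grid point and summarize spectra."""
    params = params if params is not None else ModelParameters()
    mapping = mapping if mapping is not None else calibrate()
    sim_config = sim_config if sim_config is not None else SimulationConfig(seed=spec.seed)
    if sim_config.seed != spec.seed:
        sim_config = SimulationConfig(**{**sim_config.__dict__, "seed": spec.seed})
    spectral_config = spectral_config if spectral_config is not None \
        else SpectralConfig(fs=sim_config.fs)
    points, taus = _point_parameters(spec, params, mapping)
    logger.info("sweep %s over %d points, %d repeats each",
                spec.parameter, len(points), sim_config.n_repeats)
    results = run_grid(points, sim_config)
    summaries = [summarize_traces(r.traces, spectral_config) for r in results]
    rows = []
    for value, tau, summ in zip(spec.values, taus, summaries):
        row = {spec.parameter: value, "tau_i_ms": tau,
               "peak_power": summ.peak_power, "dominant_freq_hz": summ.dominant_freq}
        for j, p in enumerate(summ.subband_powers):
            lo, hi = summ.subband_edges[j], summ.subband_edges[j + 1]
            row[f"power_{lo:g}_{hi:g}_hz"] = p
        row["total_alpha_power"] = summ.total_alpha_power
        rows.append(row)
    table = pd.DataFrame(rows)
    manifest = {
        "parameter": spec.parameter,
        "grid": list(map(float, spec.values)),
        "beta_a_fixed": spec.beta_a, "c1_fixed": spec.c1, "mu_r_fixed": spec.mu_r,
        "seed": spec.seed,
        "n_repeats": sim_config.n_repeats,
        "duration_s": sim_config.duration, "dt_s": sim_config.dt,
        "transient_s": sim_config.transient, "method": sim_config.method,
        "seeds": [r.seeds for r in results],
        "tau_i_ms": list(map(float, taus)),
        "model": {k: getattr(params, k) for k in
                  ("H_e", "H_i", "tau_e", "nu", "s0", "e0", "C2", "C3", "trn_input")},
        "mapping": {"beta_off": mapping.beta_off, "beta_max": mapping.beta_max,
                    "S_max": mapping.S_max, "S_min": mapping.S_min,
                    "r_beta": mapping.r_beta, "beta0": mapping.beta0},
        "spectral": {k: getattr(spectral_config, k) for k in
                     ("fs", "band_low", "band_high", "alpha_low", "alpha_high",
                      "filter_order", "welch_segment", "welch_overlap", "window")},
    }
    return SweepResult(spec=spec, table=table, summaries=summaries,
                       tau_i_ms=taus, manifest=manifest)


def _checked(spec: SweepSpec, expected: str) -> SweepSpec:
    if spec.parameter != expected:
        raise ConfigurationError(
            f"this driver sweeps {expected!r}, got spec for {spec.parameter!r}")
    return spec


def sweep_beta(spec: SweepSpec, **kw) -> SweepResult:
    """Amyloid-load sweep: tau_i follows the calibrated mapping."""
    return run_sweep(_checked(spec, "beta_a"), **kw)


def sweep_c1(spec: SweepSpec, **kw) -> SweepResult:
    """TCR->TRN connectivity sweep at fixed amyloid load."""
    return run_sweep(_checked(spec, "C1"), **kw)


def sweep_mu(spec: SweepSpec, **kw) -> SweepResult:
    """Sensory-drive sweep at fixed amyloid load."""
    return run_sweep(_checked(spec, "mu_r"), **kw)


def _flatten(prefix, obj, lines):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}{k}." if prefix else f"{k}.", v, lines) \
                if isinstance(v, dict) else _flatten(f"{prefix}{k}", v, lines)
    else:
        lines.append(f"{prefix} = {obj}")


def report(result: SweepResult, out_prefix, plots: bool = False) -> list:
    """Write sweep artifacts: tidy CSV, flat key-value manifest, and
    optionally PSD-overlay and sub-band bar figures.

    Returns the list of paths written.  Raises on an empty result
    before touching the filesystem.
    """
    if result.table.empty:
        raise ConfigurationError("refusing to report an empty sweep result")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = prefix.with_name(prefix.name + "_sweep.csv")
    result.table.to_csv(csv_path, index=False, float_format="%.12g")
    written.append(csv_path)
    manifest_path = prefix.with_name(prefix.name + "_manifest.txt")
    lines = []
    _flatten("", result.manifest, lines)
    manifest_path.write_text("\n".join(lines) + "\n")
    written.append(manifest_path)
    if plots:
        written.extend(_plot(result, prefix))
    return written


def _plot(result: SweepResult, prefix: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    name = result.spec.parameter
    written = []
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for value, summ in zip(result.spec.values, result.summaries):
        sel = summ.freqs <= 30
        ax.plot(summ.freqs[sel], summ.psd[sel], label=f"{name} = {value:g}")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (mV$^2$/Hz)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    p = prefix.with_name(prefix.name + "_psd.png")
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    n_pts = len(result.summaries)
    edges = result.summaries[0].subband_edges
    centers = (edges[:-1] + edges[1:]) / 2
    width = 0.8 / n_pts
    for j, (value, summ) in enumerate(zip(result.spec.values, result.summaries)):
        ax.bar(centers + (j - n_pts / 2 + 0.5) * width, summ.subband_powers,
               width=width, label=f"{name} = {value:g}")
    ax.set_xlabel("alpha sub-band centre (Hz)")
    ax.set_ylabel("integrated power (mV$^2$)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    p = prefix.with_name(prefix.name + "_subbands.png")
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
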