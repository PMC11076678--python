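"""Amyloid load to inhibitory time constant mapping.

Amyloid burden is summarized by a single PET-derived scalar, the
standardized uptake value ratio (SUVR), written ``beta_a``.  A
calibrated decreasing logistic ``S1`` converts the load into a
synaptic rate; its reciprocal is the inhibitory time constant of the
thalamic reticular nucleus:

    S1(b) = S_min + (S_max - S_min) / (1 + exp(r_beta * (b - beta0)))
    tau_i(b) = 1 / S1(b)            for b >= beta_off
    tau_i(b) = 1 / S_max            for b <  beta_off (clinically normal)

The slope and midpoint are calibrated from the clinical cutoff
``beta_off`` and the population maximum ``beta_max``:

    r_beta = 2 ln(S_max) / (beta_off - beta_max)
    beta0  = (beta_off + beta_max) / 2

With the default constants (beta_off = 1.4, beta_max = 2.65,
S_max = 0.07 ms^-1, S_min = 0.02 ms^-1) the time constant runs from
1/0.07 ≈ 14.29 ms in amyloid-negative tissue up to, but never beyond,
1/0.02 = 50 ms at extreme load.  Below the cutoff the healthy value is
clamped: sub-threshold amyloid is treated as having no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "AbetaMappingParameters",
    "calibrate",
    "transfer",
    "tau_i_of_beta",
    "severity_band",
    "solve_beta_for_tau",
]


@dataclass(frozen=True)
class AbetaMappingParameters:
    """Constants and derived calibration of the amyloid transfer.

    ``r_beta`` and ``beta0`` are derived by :func:`calibrate`; build
    instances through it rather than directly.
    """

    beta_off: float  # clinical cutoff SUVR separating normal from pathological
    beta_max: float  # maximum population SUVR
    S_max: float     # maximum transfer rate, ms^-1 (tau_i floor = 1/S_max)
    S_min: float     # minimum transfer rate, ms^-1 (tau_i ceiling = 1/S_min)
    r_beta: float    # calibrated sigmoid slope
    beta0: float     # calibrated sigmoid midpoint, SUVR

    @property
    def tau_min_ms(self) -> float:
        return 1.0 / self.S_max

    @property
    def tau_max_ms(self) -> float:
        return 1.0 / self.S_min


def calibrate(
    beta_off: float = 1.4,
    beta_max: float = 2.65,
    S_max: float = 0.07,
    S_min: float = 0.02,
) -> AbetaMappingParameters:
    """Calibrate the amyloid transfer sigmoid.

    The slope is chosen so that the logistic has essentially saturated
    at the two anchors ``beta_off`` and ``beta_max``, and the midpoint
    sits halfway between them.

    Raises
    ------
    ConfigurationError
        If ``beta_off >= beta_max`` or the rates do not satisfy
        ``0 < S_min < S_max < 1``.
    """
    if not beta_off < beta_max:
        raise ConfigurationError(
            f"beta_off must be < beta_max, got beta_off={beta_off}, beta_max={beta_max}"
        )
    if not 0.0 < S_min:
        raise ConfigurationError(f"S_min must be > 0, got S_min={S_min}")
    if not S_min < S_max:
        raise ConfigurationError(f"S_min must be < S_max, got S_min={S_min}, S_max={S_max}")
    if not S_max < 1.0:
        raise ConfigurationError(f"S_max must be < 1, got S_max={S_max}")
    r_beta = 2.0 * np.log(S_max) / (beta_off - beta_max)
    beta0 = (beta_off + beta_max) / 2.0
    return AbetaMappingParameters(
        beta_off=beta_off, beta_max=beta_max, S_max=S_max, S_min=S_min,
        r_beta=r_beta, beta0=beta0,
    )


def transfer(beta_a, cal: AbetaMappingParameters):
    """Decreasing logistic from SUVR to synaptic rate (ms^-1).

    Strictly decreasing, bounded in ``(S_min, S_max)``, with
    ``transfer(beta0) == (S_max + S_min) / 2`` exactly.  Accepts
    scalars or arrays.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    out = cal.S_min + (cal.S_max - cal.S_min) * expit(-cal.r_beta * (beta_a - cal.beta0))
    return float(out) if out.ndim == 0 else out


def tau_i_of_beta(beta_a, cal: AbetaMappingParameters):
    """Inhibitory time constant (ms) for a given amyloid load.

    Below the clinical cutoff the healthy value ``1/S_max`` is
    returned unchanged; at and above it the reciprocal of the transfer
    sigmoid applies.  Non-decreasing in ``beta_a`` and confined to
    ``[1/S_max, 1/S_min]``.  Accepts scalars or arrays.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    tau = np.where(beta_a < cal.beta_off, cal.tau_min_ms, 1.0 / transfer(beta_a, cal))
    return float(tau) if tau.ndim == 0 else tau


def solve_beta_for_tau(tau_ms: float, cal: AbetaMappingParameters,
                       lo: float = None, hi: float = 5.0) -> float:
    """Smallest amyloid load at which ``tau_i`` reaches ``tau_ms``.

    Root-finds (bisection-type bracketing) on the monotone mapping over
    ``[beta_off, hi]``.  Raises :class:`ConfigurationError` when the
    requested value is outside the attainable range on the bracket.
    """
    if lo is None:
        lo = cal.beta_off
    f = lambda b: tau_i_of_beta(b, cal) - tau_ms
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigurationError(
            f"tau_i = {tau_ms} ms is not reached on beta_a in [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


#: Severity band edges in SUVR units: the clinical cutoff, the upper
#: edge of the moderate band, and the upper edge of moderate-to-severe.
SEVERITY_EDGES = (1.4, 1.95, 2.15)


def severity_band(beta_a: float) -> str:
    """Clinical severity label for an amyloid load.

    ``normal`` below the 1.4 cutoff; ``moderate`` on [1.4, 1.95];
    ``moderate_severe`` on (1.95, 2.15]; ``severe`` above 2.15.
    """
    if not np.isfinite(beta_a):
        raise ConfigurationError(f"beta_a must be finite, got {beta_a}")
    lo, mid, hi = SEVERITY_EDGES
    if beta_a < lo:
        return "normal"
    if beta_a <= mid:
        return "moderate"
    if beta_a <= hi:
        return "moderate_severe"
    return "severe"
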