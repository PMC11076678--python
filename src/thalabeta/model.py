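"""Three-population thalamocortical neural-mass model.

The model describes the average membrane potential of three neuronal
populations — a retinal relay stage, the thalamocortical relay nucleus
(TCR, excitatory) and the thalamic reticular nucleus (TRN, inhibitory) —
each represented by a critically damped second-order synaptic kernel and
a sigmoidal potential-to-rate conversion.  The TCR excites the TRN
(gain ``C1``); the TRN inhibits the TCR (gain ``C2``); the retinal stage
feeds the TCR (gain ``C3``) and is itself driven by an exogenous input
``P(t)`` (Gaussian white noise in the simulations).

State layout (six variables, two per population)::

    x_ret1, x_ret2   retinal potential (mV) and its time derivative
    x_tcr1, x_tcr2   relay-nucleus potential and derivative
    x_trn1, x_trn2   reticular-nucleus potential and derivative

Time constants are stored in milliseconds, matching the way they are
conventionally tabulated; the right-hand side converts them to seconds
once so that all rates are in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InvalidStateError

__all__ = [
    "ModelParameters",
    "NeuralState",
    "sigmoid_rate",
    "derivatives",
    "output_potential",
    "make_batch_rhs",
]

#: Default inhibitory time constant (ms): the reciprocal of the maximum
#: amyloid transfer rate, i.e. the healthy / amyloid-unaffected value.
TAU_I_HEALTHY_MS = 1.0 / 0.07


@dataclass(frozen=True)
class ModelParameters:
    """Synaptic, connectivity and sigmoid constants of the model.

    Parameters
    ----------
    H_e, H_i : float
        Excitatory / inhibitory postsynaptic gain, mV.
    tau_e, tau_i : float
        Excitatory / inhibitory synaptic time constant, ms.  ``tau_i``
        is normally set from the amyloid load via
        :func:`thalabeta.abeta.tau_i_of_beta`.
    nu : float
        Sigmoid slope, mV^-1.
    s0 : float
        Sigmoid firing threshold, mV.
    e0 : float
        Half of the maximum population firing rate, s^-1.
    C1, C2, C3 : float
        Dimensionless connectivity gains: TCR->TRN excitation,
        TRN->TCR inhibition, retinal input to TCR.
    mu_r : float
        Mean of the exogenous drive P(t), spikes/s, constrained to
        [0, 100].
    phi_r : float
        Variance of the exogenous drive, (spikes/s)^2.
    trn_input : str
        Source population feeding the TRN sigmoid: ``"tcr"`` (the
        stated circuit, default) or ``"trn_self"`` (the literal
        self-input variant).
    """

    H_e: float = 3.25
    H_i: float = 22.0
    tau_e: float = 10.0
    tau_i: float = TAU_I_HEALTHY_MS
    nu: float = 0.56
    s0: float = 6.0
    e0: float = 25.0
    C1: float = 35.0
    C2: float = 15.0
    C3: float = 7.0
    mu_r: float = 86.0
    phi_r: float = 1.0
    trn_input: str = "tcr"

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "e0", "nu"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("C1", "C2", "C3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.mu_r <= 100.0:
            raise ConfigurationError(f"mu_r must lie in [0, 100], got {self.mu_r}")
        if self.phi_r < 0:
            raise ConfigurationError(f"phi_r must be >= 0, got {self.phi_r}")
        if self.trn_input not in ("tcr", "trn_self"):
            raise ConfigurationError(
                f"trn_input must be 'tcr' or 'trn_self', got {self.trn_input!r}"
            )

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class NeuralState:
    """The six state variables (three populations, two orders each)."""

    x_ret1: float = 0.0
    x_ret2: float = 0.0
    x_tcr1: float = 0.0
    x_tcr2: float = 0.0
    x_trn1: float = 0.0
    x_trn2: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.x_ret1, self.x_ret2, self.x_tcr1, self.x_tcr2, self.x_trn1, self.x_trn2],
            dtype=float,
        )

    @classmethod
    def from_array(cls, a) -> "NeuralState":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise InvalidStateError(f"state array must have shape (6,), got {a.shape}")
        return cls(*a)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.to_array())):
            raise InvalidStateError(f"state contains non-finite values: {self}")


def sigmoid_rate(v, params: ModelParameters):
    """Convert a membrane potential (mV) to a firing rate (s^-1).

    S(v) = 2*e0 / (1 + exp(-nu*(v - s0))): a logistic curve through
    ``e0`` at the threshold ``s0``, saturating at ``2*e0``.

    Accepts scalars or arrays.  Raises :class:`InvalidStateError` on
    non-finite input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidStateError("membrane potential must be finite")
    out = 2.0 * params.e0 * expit(params.nu * (v - params.s0))
    return float(out) if out.ndim == 0 else out


def output_potential(state, params: ModelParameters):
    """Model output signal: the potential ``C3*x_ret1 - C2*x_trn1`` (mV).

    This is the net input combination delivered to the relay nucleus —
    retinal excitation minus reticular inhibition — and is the
    EEG-like signal analysed throughout.
    """
    if isinstance(state, NeuralState):
        state.validate()
        x_ret1, x_trn1 = state.x_ret1, state.x_trn1
    else:
        a = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(a)):
            raise InvalidStateError("state contains non-finite values")
        x_ret1, x_trn1 = a[..., 0], a[..., 4]
    return params.C3 * x_ret1 - params.C2 * x_trn1


def make_batch_rhs(params: ModelParameters, tau_i_ms=None, C1=None):
    """Build a vectorized right-hand-side function for the ODE system.

    Returns ``rhs(y, p, out)`` operating on a state block ``y`` of
    shape ``(6, m)`` with per-column drive ``p`` of shape ``(m,)``,
    writing the derivatives into ``out``.  ``tau_i_ms`` and ``C1`` may
    be per-column arrays to integrate many parameter points in one
    pass; they default to the scalar values in ``params``.
    """
    tau_e = params.tau_e / 1000.0
    tau_i = np.asarray(params.tau_i if tau_i_ms is None else tau_i_ms, dtype=float) / 1000.0
    c1 = np.asarray(params.C1 if C1 is None else C1, dtype=float)
    if np.any(tau_i <= 0):
        raise ConfigurationError("tau_i must be > 0")
    a_e = params.H_e / tau_e
    b_e = 2.0 / tau_e
    c_e = 1.0 / tau_e**2
    a_i = params.H_i / tau_i
    b_i = 2.0 / tau_i
    c_i = 1.0 / tau_i**2
    two_e0 = 2.0 * params.e0
    nu, s0 = params.nu, params.s0
    C2, C3 = params.C2, params.C3
    trn_from_tcr = params.trn_input == "tcr"

    def rhs(y, p, out):
        x_ret1, x_ret2, x_tcr1, x_tcr2, x_trn1, x_trn2 = y
        s_tcr = two_e0 * expit(nu * ((C3 * x_ret1 - C2 * x_trn1) - s0))
        v_trn = x_tcr1 if trn_from_tcr else x_trn1
        s_trn = two_e0 * expit(nu * (c1 * v_trn - s0))
        out[0] = x_ret2
        out[1] = a_e * p - b_e * x_ret2 - c_e * x_ret1
        out[2] = x_tcr2
        out[3] = a_e * s_tcr - b_e * x_tcr2 - c_e * x_tcr1
        out[4] = x_trn2
        out[5] = a_i * s_trn - b_i * x_trn2 - c_i * x_trn1
        return out

    return rhs


def derivatives(state: NeuralState, t: float, params: ModelParameters, p_drive: float) -> NeuralState:
    """Evaluate the time derivatives of the six state variables.

    The retinal stage is a linear second-order filter of the exogenous
    drive ``p_drive``; the TCR and TRN stages are second-order filters
    of their sigmoidally converted synaptic inputs.  Deterministic
    given ``(state, t, p_drive)`` — the system is autonomous, ``t`` is
    accepted for ODE-solver compatibility.
    """
    state.validate()
    if not np.isfinite(p_drive):
        raise InvalidStateError("p_drive must be finite")
    rhs = make_batch_rhs(params)
    y = state.to_array().reshape(6, 1)
    out = np.empty_like(y)
    rhs(y, np.array([float(p_drive)]), out)
    return NeuralState.from_array(out[:, 0])
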