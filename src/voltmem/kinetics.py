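"""Gate variables and ion-channel kinetic models.

A gating variable ``x`` (activation ``m`` or inactivation ``h``) relaxes
toward a voltage-dependent steady state with a voltage-dependent timescale::

    tau_x(V) dx/dt = x_inf(V) - x

``x_inf`` is a monotone sigmoid on [0, 1] and ``tau_x`` is positive
everywhere.  Kinetics may be specified directly in inf/tau form (sigmoid
steady state plus constant, Gaussian-bell or tabulated timescale) or as a
pair of alpha/beta transition rates, from which ``x_inf = a/(a+b)`` and
``tau = 1/(a+b)`` follow.

Timescales measured at one temperature are rescaled to a target temperature
with the standard Q10 temperature coefficient (default 3).  Gates are
classified *fast* when their timescale, evaluated at the edges of the
transition window (the voltages where ``x_inf`` crosses 0.05 and 0.95), falls
below the membrane time constant; fast gates admit the quasi-steady-state
substitution ``x ~ x_inf(V)`` that reduces the membrane ODE to one dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, VoltmemError

__all__ = [
    "SigmoidSteadyState",
    "ConstantTimescale",
    "GaussianTimescale",
    "TabulatedTimescale",
    "HHRate",
    "RatePair",
    "GateSpec",
    "ChannelModel",
    "evaluate_steady_state",
    "evaluate_timescale",
    "rescale_timescale_q10",
    "transition_window",
    "classify_fast",
]

DEFAULT_Q10 = 3.0

#: voltage range outside which physiology is not modelled (mV)
V_SCAN_RANGE = (-200.0, 200.0)


# ---------------------------------------------------------------------------
# steady-state forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidSteadyState:
    """Boltzmann sigmoid ``1 / (1 + exp(-slope * (V - v_half)))``.

    ``slope`` (1/mV) is positive for activation gates (increasing with
    depolarization) and negative for inactivation gates.
    """

    v_half: float
    slope: float

    def __post_init__(self):
        if self.slope == 0:
            raise InvalidParameterError("sigmoid slope must be nonzero")

    def __call__(self, v):
        return 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(v, float) - self.v_half)))

    def invert(self, level: float) -> float:
        """Voltage at which the sigmoid attains ``level`` in (0, 1)."""
        if not 0.0 < level < 1.0:
            raise InvalidParameterError(f"level {level} outside (0, 1)")
        return self.v_half + math.log(level / (1.0 - level)) / self.slope


# ---------------------------------------------------------------------------
# timescale forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantTimescale:
    tau_ms: float

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise InvalidParameterError("timescale must be positive")

    def __call__(self, v):
        return np.full_like(np.asarray(v, float), self.tau_ms)


@dataclass(frozen=True)
class GaussianTimescale:
    """Gaussian bell ``baseline + amplitude * exp(-((V - center)/width)^2)``."""

    amplitude_ms: float
    center_mv: float
    width_mv: float
    baseline_ms: float

    def __post_init__(self):
        if self.width_mv <= 0:
            raise InvalidParameterError("width must be positive")
        if self.baseline_ms <= 0 or self.baseline_ms + self.amplitude_ms <= 0:
            raise InvalidParameterError("timescale must stay positive for all V")

    def __call__(self, v):
        z = (np.asarray(v, float) - self.center_mv) / self.width_mv
        return self.baseline_ms + self.amplitude_ms * np.exp(-z * z)


@dataclass(frozen=True)
class TabulatedTimescale:
    voltages_mv: tuple[float, ...]
    values_ms: tuple[float, ...]

    def __post_init__(self):
        if len(self.voltages_mv) != len(self.values_ms) or len(self.values_ms) < 2:
            raise InvalidParameterError("need matching tables of length >= 2")
        if any(t <= 0 for t in self.values_ms):
            raise InvalidParameterError("tabulated timescales must be positive")
        if any(b <= a for a, b in zip(self.voltages_mv, self.voltages_mv[1:])):
            raise InvalidParameterError("voltage grid must be strictly increasing")

    def __call__(self, v):
        return np.interp(np.asarray(v, float), self.voltages_mv, self.values_ms)


# ---------------------------------------------------------------------------
# alpha/beta rate laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HHRate:
    """One transition rate in a standard Hodgkin-Huxley closed form.

    form = "sigmoid":     A / (1 + exp((V - midpoint)/scale))
    form = "exponential": A * exp((V - midpoint)/scale)
    form = "exp_linear":  A * ((V - midpoint)/scale) / (1 - exp(-(V - midpoint)/scale))

    ``rate`` A is in 1/ms, ``scale`` and ``midpoint`` in mV.  The exp-linear
    form has a removable singularity at V = midpoint where it equals A.
    """

    form: Literal["sigmoid", "exponential", "exp_linear"]
    rate: float
    scale: float
    midpoint: float

    def __post_init__(self):
        if self.form not in ("sigmoid", "exponential", "exp_linear"):
            raise InvalidParameterError(f"unknown rate form {self.form!r}")
        if self.rate <= 0:
            raise InvalidParameterError("rate amplitude must be positive")
        if self.scale == 0:
            raise InvalidParameterError("rate scale must be nonzero")

    def __call__(self, v):
        x = (np.asarray(v, float) - self.midpoint) / self.scale
        if self.form == "sigmoid":
            return self.rate / (1.0 + np.exp(x))
        if self.form == "exponential":
            return self.rate * np.exp(x)
        # exp_linear, with the x -> 0 limit handled explicitly
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            out = self.rate * x / (1.0 - np.exp(-x))
        return np.where(np.abs(x) < 1e-9, self.rate, out)


@dataclass(frozen=True)
class RatePair:
    """Forward/backward rate pair; yields inf/tau via a/(a+b) and 1/(a+b)."""

    alpha: HHRate
    beta: HHRate

    def steady_state(self, v):
        a, b = self.alpha(v), self.beta(v)
        return a / (a + b)

    def timescale(self, v):
        return 1.0 / (self.alpha(v) + self.beta(v))


# ---------------------------------------------------------------------------
# gate and channel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateSpec:
    """One activation or inactivation variable of a channel.

    Either ``steady_state_form``/``timescale_form`` or ``rates`` must be
    given; when rates are present they define both curves.
    """

    name: str
    role: Literal["activation", "inactivation"]
    exponent: int = 1
    steady_state_form: SigmoidSteadyState | None = None
    timescale_form: ConstantTimescale | GaussianTimescale | TabulatedTimescale | None = None
    rates: RatePair | None = None

    def __post_init__(self):
        if self.exponent < 1:
            raise InvalidParameterError("gate exponent must be >= 1")
        if self.role not in ("activation", "inactivation"):
            raise InvalidParameterError(f"unknown gate role {self.role!r}")
        if self.rates is None and (
            self.steady_state_form is None or self.timescale_form is None
        ):
            raise InvalidParameterError(
                "gate needs either closed inf/tau forms or an alpha/beta rate pair"
            )

    def steady_state(self, v):
        if self.rates is not None:
            return self.rates.steady_state(v)
        return self.steady_state_form(v)

    def timescale(self, v):
        if self.rates is not None:
            return self.rates.timescale(v)
        return self.timescale_form(v)


@dataclass(frozen=True)
class ChannelModel:
    """A named channel: ion selectivity, gate list, experiment temperature.

    An empty gate list makes the channel ohmic (a leak).  A channel is
    *persistent* exactly when it carries no inactivation gate.
    """

    id: str
    ion: str
    gates: tuple[GateSpec, ...] = ()
    experiment_temperature_c: float | None = None
    q10: float = DEFAULT_Q10
    fixed_reversal_mv: float | None = None  # bypasses Nernst lookup when set

    def __post_init__(self):
        object.__setattr__(self, "gates", tuple(self.gates))

    @property
    def persistent(self) -> bool:
        return not any(g.role == "inactivation" for g in self.gates)

    def tau_scale(self, target_temperature_c: float) -> float:
        """Q10 multiplier applied to every gate timescale at the target temperature."""
        if self.experiment_temperature_c is None:
            return 1.0
        return self.q10 ** ((self.experiment_temperature_c - target_temperature_c) / 10.0)

    def fast_flags(self, tau_membrane_ms: float, target_temperature_c: float | None = None,
                   strict: bool = False) -> tuple[bool, ...]:
        scale = 1.0 if target_temperature_c is None else self.tau_scale(target_temperature_c)
        return tuple(
            classify_fast(g, tau_membrane_ms, tau_scale=scale, strict=strict)
            for g in self.gates
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def evaluate_steady_state(gate: GateSpec, v):
    """Steady-state activity ``x_inf(V)`` in [0, 1]."""
    return gate.steady_state(v)


def evaluate_timescale(gate: GateSpec, v, tau_scale: float = 1.0):
    """Relaxation timescale ``tau_x(V)`` in ms, optionally Q10-rescaled."""
    return tau_scale * gate.timescale(v)


def rescale_timescale_q10(tau_ms: float, t_experiment_c: float, t_target_c: float,
                          q10: float = DEFAULT_Q10) -> float:
    """Rescale a timescale measured at ``t_experiment_c`` to ``t_target_c``.

    A ten-degree warmer target divides the timescale by Q10.
    """
    if np.any(np.asarray(tau_ms) <= 0):
        raise InvalidParameterError("tau must be positive")
    if q10 <= 0:
        raise InvalidParameterError("Q10 must be positive")
    return tau_ms * q10 ** ((t_experiment_c - t_target_c) / 10.0)


def _crossing(gate: GateSpec, level: float) -> float:
    """Voltage where x_inf crosses ``level``, by inversion or bracketed root."""
    if gate.rates is None and isinstance(gate.steady_state_form, SigmoidSteadyState):
        return gate.steady_state_form.invert(level)
    lo, hi = V_SCAN_RANGE
    f = lambda v: float(gate.steady_state(v)) - level
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise VoltmemError(
            f"gate {gate.name!r}: steady state does not cross {level} on "
            f"[{lo}, {hi}] mV; transition window undefined"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def transition_window(gate: GateSpec) -> tuple[float, float]:
    """Voltages at which ``x_inf`` crosses 0.05 and 0.95, in that order.

    For activation gates the 0.05 crossing is the more hyperpolarized
    voltage; for inactivation (decreasing) gates the order in voltage flips,
    but the return order is always (V at 5% activity, V at 95% activity).
    """
    return _crossing(gate, 0.05), _crossing(gate, 0.95)


def classify_fast(gate: GateSpec, tau_membrane_ms: float, tau_scale: float = 1.0,
                  strict: bool = False) -> bool:
    """True when the gate's effective timescale range lies below ``tau_membrane_ms``.

    The effective range is the pair of timescales at the transition-window
    endpoints (after Q10 rescaling by ``tau_scale``).  ``strict=True``
    instead requires the maximum of tau over the whole window to fall below
    the membrane time constant, which guards against interior timescale
    peaks the endpoint rule cannot see.
    """
    if tau_membrane_ms <= 0:
        raise InvalidParameterError("membrane time constant must be positive")
    v05, v95 = transition_window(gate)
    if strict:
        grid = np.linspace(min(v05, v95), max(v05, v95), 201)
        worst = float(np.max(evaluate_timescale(gate, grid, tau_scale)))
    else:
        worst = max(
            float(evaluate_timescale(gate, v05, tau_scale)),
            float(evaluate_timescale(gate, v95, tau_scale)),
        )
    return worst < tau_membrane_ms
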