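"""Membrane model assembly: Nernst reversals, the full ODE and its fast reduction.

The membrane obeys the conductance-model current balance::

    -C dV/dt = I_ext + sum_i gbar_i * m_i^a * h_i^b * (V - E_i) + gbar_leak * (V - E_leak)

with each gating variable relaxing as ``tau_x(V) dx/dt = x_inf(V) - x``.
Reversal potentials ``E_i`` come from the Nernst equation applied to an
ionic-conditions table (intracellular/extracellular concentration per
species), except for species with a fixed override such as the mixed Na+K
reversal of HCN channels.

When every gate is fast relative to the membrane RC time ``tau = C/gbar_leak``
the substitution ``x ~ x_inf(V)`` collapses the system to a scalar field
``dV/dt = f(V)`` whose roots are the resting potentials: stable where
``f'(V) < 0``.  ``reduce_fast`` produces that field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import AssemblyError, InvalidParameterError, ReductionError
from .kinetics import ChannelModel, GateSpec, classify_fast
from .units import FARADAY_F, GAS_CONSTANT_R, celsius_to_kelvin

__all__ = [
    "IonRecord",
    "IonicConditions",
    "MembraneModel",
    "PhaseField",
    "nernst",
    "build_model",
    "full_rhs",
    "reduce_fast",
]

#: physiological voltage range used throughout (mV)
PHYSIOLOGICAL_RANGE = (-140.0, 150.0)

DEFAULT_CAPACITANCE = 1.0  # uF/cm^2
DEFAULT_LEAK_CONDUCTANCE = 0.2  # mS/cm^2  (= 200 uS/cm^2)
DEFAULT_CONDUCTANCE_RATIO = 10.0  # non-leak : leak


def nernst(intracellular_mm: float, extracellular_mm: float, valence: int,
           temperature_c: float) -> float:
    """Nernst reversal potential in mV.

    E = (R T / z F) ln([out]/[in]) * 1000, with R = 8.314 J/(mol K),
    F = 96485 C/mol and T in Kelvin.
    """
    if intracellular_mm <= 0 or extracellular_mm <= 0:
        raise InvalidParameterError("ion concentrations must be positive")
    if valence == 0:
        raise InvalidParameterError("valence must be nonzero")
    t_kelvin = celsius_to_kelvin(temperature_c)
    return (
        GAS_CONSTANT_R * t_kelvin / (valence * FARADAY_F)
        * math.log(extracellular_mm / intracellular_mm)
        * 1000.0
    )


@dataclass(frozen=True)
class IonRecord:
    intracellular_mm: float
    extracellular_mm: float
    valence: int

    def __post_init__(self):
        if self.intracellular_mm <= 0 or self.extracellular_mm <= 0:
            raise InvalidParameterError("ion concentrations must be positive")
        if self.valence == 0:
            raise InvalidParameterError("valence must be nonzero")


@dataclass(frozen=True)
class IonicConditions:
    """Bath/cytoplasm ion table at a fixed temperature.

    ``fixed_reversals_mv`` holds per-species overrides that bypass Nernst,
    used for mixed-selectivity species (the HCN Na+K reversal) whose single
    -ion formula does not apply.  ``leak_species`` names the species whose
    reversal the ohmic leak adopts by default.
    """

    name: str
    temperature_c: float
    ions: Mapping[str, IonRecord]
    fixed_reversals_mv: Mapping[str, float] = field(default_factory=dict)
    leak_species: str = "Cl"

    def __post_init__(self):
        if not -50.0 < self.temperature_c < 60.0:
            raise InvalidParameterError(
                f"temperature {self.temperature_c} degC outside sanity bounds (-50, 60)"
            )

    def reversal(self, species: str) -> float:
        """Reversal potential for a species, full precision (mV)."""
        if species in self.fixed_reversals_mv:
            return float(self.fixed_reversals_mv[species])
        try:
            rec = self.ions[species]
        except KeyError:
            raise AssemblyError(
                f"no ionic record or fixed reversal for species {species!r} "
                f"in conditions {self.name!r}"
            ) from None
        return nernst(rec.intracellular_mm, rec.extracellular_mm, rec.valence,
                      self.temperature_c)

    def reversal_table(self) -> dict[str, float]:
        out = {sp: self.reversal(sp) for sp in self.ions}
        out.update({sp: float(v) for sp, v in self.fixed_reversals_mv.items()})
        return out


@dataclass(frozen=True)
class PhaseField:
    """Reduced scalar field ``dV/dt = f(V)`` for a fast (or forced) reduction."""

    f: Callable[[np.ndarray], np.ndarray]
    v_range: tuple[float, float] = PHYSIOLOGICAL_RANGE
    reduced_gates: tuple[str, ...] = ()
    approximate: bool = False  # True when slow gates were reduced by force

    def __call__(self, v):
        return self.f(np.asarray(v, float))


@dataclass(frozen=True)
class MembraneModel:
    """Assembled single-cell conductance model.

    ``channels`` pairs each :class:`ChannelModel` with its maximal
    conductance in mS/cm^2.  Gate timescales are Q10-rescaled from each
    channel's experiment temperature to the conditions temperature.
    """

    channels: tuple[tuple[ChannelModel, float], ...]
    leak_conductance: float  # mS/cm^2
    leak_reversal: float  # mV
    capacitance: float  # uF/cm^2
    reversal_map: Mapping[str, float]
    temperature_c: float
    conditions_name: str = ""

    def __post_init__(self):
        if self.capacitance <= 0:
            raise InvalidParameterError("capacitance must be positive")
        if self.leak_conductance <= 0:
            raise InvalidParameterError("leak conductance must be positive")
        object.__setattr__(self, "channels", tuple(self.channels))
        for ch, g in self.channels:
            if g < 0:
                raise InvalidParameterError(f"negative conductance for {ch.id}")
            if ch.ion not in self.reversal_map:
                raise AssemblyError(
                    f"channel {ch.id!r}: species {ch.ion!r} missing from reversal map"
                )

    # -- structure ---------------------------------------------------------

    @property
    def tau_membrane(self) -> float:
        """Linear membrane time constant C/gbar_leak in ms."""
        return self.capacitance / self.leak_conductance

    @property
    def gate_index(self) -> list[tuple[int, str, GateSpec]]:
        """Flat list of (channel position, qualified name, gate)."""
        out = []
        for ci, (ch, _g) in enumerate(self.channels):
            for gate in ch.gates:
                out.append((ci, f"{ch.id}.{gate.name}", gate))
        return out

    @property
    def n_gates(self) -> int:
        return sum(len(ch.gates) for ch, _ in self.channels)

    @property
    def gate_names(self) -> list[str]:
        return [name for _, name, _ in self.gate_index]

    def tau_scales(self) -> list[float]:
        """Per-gate Q10 multipliers at the model temperature."""
        return [
            self.channels[ci][0].tau_scale(self.temperature_c)
            for ci, _, _ in self.gate_index
        ]

    def steady_gates(self, v: float) -> np.ndarray:
        """All gate variables at steady state for voltage ``v``."""
        return np.array([float(g.steady_state(v)) for _, _, g in self.gate_index])

    # -- dynamics ----------------------------------------------------------

    def membrane_current(self, v, gates: Sequence[float]) -> float:
        """Total ionic current density (uA/cm^2), leak included, I_ext excluded."""
        i = self.leak_conductance * (v - self.leak_reversal)
        k = 0
        for ch, gbar in self.channels:
            open_frac = 1.0
            for gate in ch.gates:
                open_frac *= gates[k] ** gate.exponent
                k += 1
            i += gbar * open_frac * (v - self.reversal_map[ch.ion])
        return i

    def rhs(self, state: np.ndarray, i_ext: float = 0.0) -> np.ndarray:
        """Time derivative of (V, gates...); ``i_ext`` in uA/cm^2."""
        v = state[0]
        gates = state[1:]
        dv = -(i_ext + self.membrane_current(v, gates)) / self.capacitance
        out = np.empty_like(state)
        out[0] = dv
        scales = self.tau_scales()
        for k, (_, _, gate) in enumerate(self.gate_index):
            tau = scales[k] * float(gate.timescale(v))
            out[1 + k] = (float(gate.steady_state(v)) - gates[k]) / tau
        return out

    def fast_flags(self, strict: bool = False) -> list[bool]:
        scales = self.tau_scales()
        return [
            classify_fast(gate, self.tau_membrane, tau_scale=scales[k], strict=strict)
            for k, (_, _, gate) in enumerate(self.gate_index)
        ]


def build_model(channels: Sequence[ChannelModel | tuple[ChannelModel, float | None]],
                conditions: IonicConditions,
                capacitance: float = DEFAULT_CAPACITANCE,
                leak_conductance: float = DEFAULT_LEAK_CONDUCTANCE,
                leak_reversal: float | None = None,
                default_ratio: float = DEFAULT_CONDUCTANCE_RATIO) -> MembraneModel:
    """Assemble channels plus an ohmic leak under an ionic-conditions preset.

    Channels may be given bare or as (channel, gbar) pairs; a missing or
    ``None`` conductance defaults to ``default_ratio * leak_conductance``
    (the standard 10:1 overexpression ratio).  The leak reversal defaults to
    the preset's leak species (chloride in both shipped presets).  Reversals
    are computed at full precision; rounding is a display concern only.
    """
    resolved: list[tuple[ChannelModel, float]] = []
    for entry in channels:
        if isinstance(entry, ChannelModel):
            ch, g = entry, None
        else:
            ch, g = entry
        if g is None:
            g = default_ratio * leak_conductance
        resolved.append((ch, float(g)))

    reversal_map = conditions.reversal_table()
    for ch, _ in resolved:
        if ch.fixed_reversal_mv is not None:
            reversal_map[ch.ion] = float(ch.fixed_reversal_mv)
        elif ch.ion not in reversal_map:
            raise AssemblyError(
                f"channel {ch.id!r}: species {ch.ion!r} not present in "
                f"conditions {conditions.name!r} and no fixed reversal given"
            )
    if leak_reversal is None:
        leak_reversal = conditions.reversal(conditions.leak_species)

    return MembraneModel(
        channels=tuple(resolved),
        leak_conductance=leak_conductance,
        leak_reversal=float(leak_reversal),
        capacitance=capacitance,
        reversal_map=reversal_map,
        temperature_c=conditions.temperature_c,
        conditions_name=conditions.name,
    )


def full_rhs(model: MembraneModel, state: Sequence[float], i_ext: float = 0.0) -> np.ndarray:
    """Functional alias for :meth:`MembraneModel.rhs`."""
    return model.rhs(np.asarray(state, float), i_ext)


def reduce_fast(model: MembraneModel, force: bool = False,
                i_ext: float = 0.0) -> PhaseField:
    """Collapse all gates to their steady-state curves, yielding ``f(V)``.

    Valid when every gate is fast (timescale below the membrane time
    constant at its transition-window edges).  A slow gate raises
    :class:`ReductionError` naming the offender unless ``force=True``, in
    which case the field is returned marked ``approximate`` — its roots are
    still the exact equilibria of the full system, but transient dynamics
    and basin boundaries are not captured.
    """
    flags = model.fast_flags()
    names = model.gate_names
    slow = [n for n, fast in zip(names, flags) if not fast]
    if slow and not force:
        raise ReductionError(
            f"cannot reduce: slow gate(s) {', '.join(slow)} "
            f"(tau above membrane time constant {model.tau_membrane:g} ms); "
            "pass force=True for an approximate reduction"
        )

    channel_terms = []
    for ch, gbar in model.channels:
        e_rev = model.reversal_map[ch.ion]
        channel_terms.append((ch.gates, gbar, e_rev))

    def f(v):
        v = np.asarray(v, float)
        i = model.leak_conductance * (v - model.leak_reversal)
        for gates, gbar, e_rev in channel_terms:
            open_frac = np.ones_like(v)
            for gate in gates:
                open_frac = open_frac * gate.steady_state(v) ** gate.exponent
            i = i + gbar * open_frac * (v - e_rev)
        return -(i_ext + i) / model.capacitance

    return PhaseField(
        f=f,
        v_range=PHYSIOLOGICAL_RANGE,
        reduced_gates=tuple(names),
        approximate=bool(slow),
    )
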