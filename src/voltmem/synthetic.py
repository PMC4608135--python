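"""Synthetic channel generation for screens, tests and demonstrations.

A :class:`SyntheticChannelSpec` fixes the designed properties of a channel
(ion, gate role, sigmoid shape, timescale); any field left ``None`` is drawn
from a seeded generator within physiologically plausible ranges, so an
ensemble of random-but-reasonable channels can be produced reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .kinetics import (
    ChannelModel,
    ConstantTimescale,
    GateSpec,
    SigmoidSteadyState,
)

__all__ = ["SyntheticChannelSpec", "generate_synthetic_channel"]

#: sampling ranges for unspecified parameters
V_HALF_RANGE = (-80.0, 20.0)  # mV
SLOPE_RANGE = (0.05, 0.3)  # 1/mV (magnitude)
TAU_RANGE = (0.5, 50.0)  # ms


@dataclass(frozen=True)
class SyntheticChannelSpec:
    """Design parameters of a synthetic channel; ``None`` fields are randomized."""

    id: str
    ion: str = "Na"
    role: Literal["activation", "inactivation"] = "activation"
    v_half: float | None = None  # mV
    slope: float | None = None  # 1/mV magnitude; sign set by direction
    tau_ms: float | None = None
    exponent: int = 1
    direction: Literal["increasing", "decreasing"] | None = None
    fixed_reversal_mv: float | None = None
    experiment_temperature_c: float = 23.0


def generate_synthetic_channel(spec: SyntheticChannelSpec, seed: int) -> ChannelModel:
    """Build a channel from a spec, drawing unset parameters from ``seed``.

    Deterministic: the same (spec, seed) pair always yields the same model.
    By default activation gates get increasing sigmoids and inactivation
    gates decreasing ones; ``spec.direction`` overrides (a decreasing
    activation gate models an inward-rectifier-style channel).
    """
    rng = np.random.default_rng(seed)
    # draw in fixed order so that specifying one field never shifts another
    draw_vhalf = rng.uniform(*V_HALF_RANGE)
    draw_slope = rng.uniform(*SLOPE_RANGE)
    draw_tau = rng.uniform(*TAU_RANGE)

    v_half = spec.v_half if spec.v_half is not None else float(draw_vhalf)
    slope_mag = abs(spec.slope) if spec.slope is not None else float(draw_slope)
    tau = spec.tau_ms if spec.tau_ms is not None else float(draw_tau)

    direction = spec.direction
    if direction is None:
        direction = "increasing" if spec.role == "activation" else "decreasing"
    slope = slope_mag if direction == "increasing" else -slope_mag

    gate = GateSpec(
        name="m" if spec.role == "activation" else "h",
        role=spec.role,
        exponent=spec.exponent,
        steady_state_form=SigmoidSteadyState(v_half=v_half, slope=slope),
        timescale_form=ConstantTimescale(tau),
    )
    return ChannelModel(
        id=spec.id,
        ion=spec.ion,
        gates=(gate,),
        experiment_temperature_c=spec.experiment_temperature_c,
        fixed_reversal_mv=spec.fixed_reversal_mv,
    )
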