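"""Combinatorial channel screens and conductance-space memory maximization.

A screen enumerates unordered channel combinations at requested arities
(X + leak, X + Y + leak, optionally with a mandatory anchor such as a
persistent sodium channel or an inward rectifier), simulates a descending
clamp sweep for each, classifies the outcome, and tabulates bistable sets
with their memory loci — the machine twin of a tabulated screen.

``maximize_memories`` addresses the design question argmax_g |r(f(V, g))|:
over a box of maximal-conductance vectors for all-fast channel sets, count
stable roots of the reduced field on a deterministic grid and return a
maximizer (ties broken toward the smallest total conductance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ReductionError, VoltmemError
from .kinetics import ChannelModel
from .membrane import (
    DEFAULT_CAPACITANCE,
    DEFAULT_CONDUCTANCE_RATIO,
    DEFAULT_LEAK_CONDUCTANCE,
    IonicConditions,
    MembraneModel,
    build_model,
    reduce_fast,
)
from .protocols import Protocol, make_sweep_protocol, simulate
from .stability import AttractorReport, classify, detect_attractors, phase_portrait

__all__ = [
    "ScreenSpec",
    "ScreenResult",
    "enumerate_combinations",
    "run_screen",
    "sweep_and_classify",
    "maximize_memories",
]

#: relaxation is extended up to this horizon for epochs that have not settled
MAX_RELAXATION_MS = 10_000.0


@dataclass(frozen=True)
class ScreenSpec:
    """Specification of a combinatorial screen.

    ``pool`` is the candidate channel list; ``arities`` the sizes of the
    free slots (1 = X + leak, 2 = X + Y + leak, ...); ``anchor`` an optional
    channel added to every combination (and excluded from the free slots).
    Every combination additionally receives the ohmic leak.
    """

    pool: tuple[ChannelModel, ...]
    conditions: IonicConditions
    arities: tuple[int, ...] = (1,)
    anchor: ChannelModel | None = None
    conductance_ratio: float = DEFAULT_CONDUCTANCE_RATIO
    leak_conductance: float = DEFAULT_LEAK_CONDUCTANCE
    capacitance: float = DEFAULT_CAPACITANCE

    def __post_init__(self):
        object.__setattr__(self, "pool", tuple(self.pool))
        object.__setattr__(self, "arities", tuple(self.arities))
        if not self.pool:
            raise InvalidParameterError("channel pool must be nonempty")
        if any(a < 1 for a in self.arities):
            raise InvalidParameterError("arities must be >= 1")
        if self.anchor is not None and self.anchor.id not in [c.id for c in self.pool]:
            raise InvalidParameterError(
                f"anchor {self.anchor.id!r} must be a member of the pool"
            )


@dataclass
class ScreenResult:
    spec: ScreenSpec
    rows: list[dict]
    reports: dict[str, AttractorReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def bistable_table(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["classification"] == "bistable"].reset_index(drop=True)


def enumerate_combinations(spec: ScreenSpec) -> list[tuple[ChannelModel, ...]]:
    """All unordered channel subsets at the requested arities.

    Combinations are sets (no permutation duplicates), listed in
    deterministic lexicographic order of channel ids; the anchor, when set,
    is appended to every combination and excluded from the free slots.
    """
    free = sorted(
        (c for c in spec.pool if spec.anchor is None or c.id != spec.anchor.id),
        key=lambda c: c.id,
    )
    out: list[tuple[ChannelModel, ...]] = []
    for arity in spec.arities:
        for combo in itertools.combinations(free, arity):
            members = tuple(combo) + ((spec.anchor,) if spec.anchor else ())
            out.append(members)
    return out


def combo_label(channels: Sequence[ChannelModel]) -> str:
    return " + ".join([c.id for c in channels] + ["leak"])


def sweep_and_classify(model: MembraneModel, protocol: Protocol | None = None,
                       extend_unsettled: bool = True) -> tuple[AttractorReport, str]:
    """Run the standard descending clamp sweep and classify the outcome.

    Epochs that fail the convergence criterion are retried with the
    relaxation period extended to the 10 s decision horizon; what has not
    settled by then is reported non-convergent.
    """
    if protocol is None:
        protocol = make_sweep_protocol()
    traj = simulate(model, protocol)
    report = detect_attractors(traj)
    if extend_unsettled and report.n_nonconvergent > 0:
        ep0 = protocol.epochs[0]
        long_release = MAX_RELAXATION_MS - ep0.clamp_ms
        if long_release > ep0.release_ms:
            retry = Protocol(tuple(
                type(ep)(ep.command_voltage, ep.clamp_ms, long_release,
                         ep.clamp_conductance)
                for ep in protocol.epochs
            ), continuous=protocol.continuous)
            traj = simulate(model, retry, sample_ms=0.5)
            report = detect_attractors(traj)
    return report, classify(report)


def run_screen(spec: ScreenSpec, protocol: Protocol | None = None) -> ScreenResult:
    """Simulate and classify every combination in a screen.

    Per-combination simulation failures are recorded in the result row
    (classification "error") rather than aborting the screen.
    """
    rows: list[dict] = []
    reports: dict[str, AttractorReport] = {}
    for combo in enumerate_combinations(spec):
        label = combo_label(combo)
        try:
            model = build_model(
                list(combo), spec.conditions,
                capacitance=spec.capacitance,
                leak_conductance=spec.leak_conductance,
                default_ratio=spec.conductance_ratio,
            )
            report, label_cls = sweep_and_classify(model, protocol)
            reports[label] = report
            rows.append({
                "combination": label,
                "conditions": spec.conditions.name,
                "classification": label_cls,
                "n_loci": len(report.loci),
                "loci_mv": tuple(report.loci_rounded),
                "n_nonconvergent": report.n_nonconvergent,
            })
        except VoltmemError as exc:
            rows.append({
                "combination": label,
                "conditions": spec.conditions.name,
                "classification": "error",
                "n_loci": 0,
                "loci_mv": (),
                "n_nonconvergent": -1,
                "error": str(exc),
            })
    return ScreenResult(spec=spec, rows=rows, reports=reports)


def maximize_memories(channels: Sequence[ChannelModel], conditions: IonicConditions,
                      bounds: Mapping[str, tuple[float, float]] | tuple[float, float] = (0.0, 4.0),
                      resolution: int = 21,
                      leak_conductance: float = DEFAULT_LEAK_CONDUCTANCE,
                      capacitance: float = DEFAULT_CAPACITANCE,
                      grid_step: float = 0.5) -> tuple[dict[str, float], int]:
    """Deterministic grid search for the conductance vector with most memories.

    Requires every gate of every channel to be fast (the memory count is the
    stable-root count of the reduced field, which is only exact then); a
    slow gate raises :class:`ReductionError`.  ``bounds`` is either one
    (lo, hi) box applied to all channels or a per-channel-id mapping.
    Returns ``({channel id: gbar}, memory_count)`` with ties broken toward
    the smallest total conductance (then lexicographically), so the result
    is reproducible.
    """
    if resolution < 2:
        raise InvalidParameterError("resolution must be >= 2")
    axes = []
    for ch in channels:
        lo, hi = bounds[ch.id] if isinstance(bounds, Mapping) else bounds
        axes.append(np.linspace(lo, hi, resolution))

    best_vec: dict[str, float] | None = None
    best_count = -1
    best_total = np.inf
    for point in itertools.product(*axes):
        model = build_model(
            [(ch, g) for ch, g in zip(channels, point)], conditions,
            capacitance=capacitance, leak_conductance=leak_conductance,
        )
        try:
            phase_field = reduce_fast(model)
        except ReductionError:
            raise
        portrait = phase_portrait(phase_field, grid_step=grid_step)
        count = portrait.memory_count
        total = float(sum(point))
        if count > best_count or (count == best_count and total < best_total):
            best_count = count
            best_total = total
            best_vec = {ch.id: float(g) for ch, g in zip(channels, point)}
    return best_vec, best_count
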