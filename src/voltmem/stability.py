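"""Attractor detection, classification and phase-portrait analysis.

Two complementary routes to the resting structure of a model:

* **Simulation**: run a clamp sweep, test each epoch's release phase for
  convergence (|dV/dt| below threshold over a settling window), and cluster
  the settled voltages into attractor loci.
* **Phase portrait**: for a fast-reduced field ``f(V)``, scan for sign
  changes on a voltage grid, refine each root by bisection, and read
  stability off the slope — ``f'(V*) < 0`` marks an attractor.

For all-fast models the two routes must agree: a 1-D flow cannot cross a
fixed point, so every release voltage settles into the nearest stable root
on its own side.  Slow gates break this — the trajectory can *overshoot* a
nearby attractor while a slow variable decays — which
:func:`basin_map_consistency` detects by comparing attained attractors with
nearest stable roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, VoltmemError
from .membrane import PHYSIOLOGICAL_RANGE, PhaseField

__all__ = [
    "AttractorReport",
    "PhasePortrait",
    "Root",
    "detect_attractors",
    "phase_portrait",
    "basin_map_consistency",
    "classify",
]

#: an epoch counts as settled when max |dV/dt| over the window is below this (mV/ms)
CONVERGENCE_THRESHOLD = 1e-4
DEFAULT_SETTLE_WINDOW_MS = 100.0
DEFAULT_CLUSTER_TOL_MV = 1.0
ROOT_TOL_MV = 1e-6

Stability = Literal["stable", "unstable", "half-stable"]


@dataclass(frozen=True)
class Root:
    voltage: float
    stability: Stability


@dataclass
class PhasePortrait:
    """Roots and stability structure of a reduced field on a voltage grid."""

    grid: np.ndarray
    values: np.ndarray
    roots: list[Root]

    @property
    def stable_roots(self) -> list[float]:
        return [r.voltage for r in self.roots if r.stability == "stable"]

    @property
    def memory_count(self) -> int:
        """Number of attractors |r(f)| — stable transversal roots only."""
        return len(self.stable_roots)


@dataclass
class AttractorReport:
    """Clustered attractor loci from a trajectory ensemble.

    ``basin_map`` maps each epoch's command voltage to a locus index, or to
    ``None`` for epochs that failed the convergence criterion.  Loci keep
    full precision; ``loci_rounded`` gives the nearest-mV display values.
    """

    loci: list[float]
    basin_map: dict[float, int | None]
    settle_stats: list[dict]
    cluster_tol_mv: float = DEFAULT_CLUSTER_TOL_MV

    @property
    def loci_rounded(self) -> list[int]:
        return [int(round(v)) for v in self.loci]

    @property
    def n_nonconvergent(self) -> int:
        return sum(1 for v in self.basin_map.values() if v is None)


def _single_linkage_1d(values: np.ndarray, tol: float) -> tuple[np.ndarray, list[float]]:
    """Single-linkage clustering on a line: split sorted values at gaps > tol."""
    order = np.argsort(values)
    labels = np.empty(len(values), int)
    centers: list[float] = []
    cluster_members: list[list[int]] = []
    prev = None
    for idx in order:
        if prev is None or values[idx] - prev > tol:
            cluster_members.append([idx])
        else:
            cluster_members[-1].append(idx)
        prev = values[idx]
    for ci, members in enumerate(cluster_members):
        labels[members] = ci
        centers.append(float(np.mean(values[members])))
    return labels, centers


def detect_attractors(trajectories, tolerance: float = DEFAULT_CLUSTER_TOL_MV,
                      settle_window_ms: float = DEFAULT_SETTLE_WINDOW_MS,
                      threshold: float = CONVERGENCE_THRESHOLD) -> AttractorReport:
    """Find attractor loci from one or more multi-epoch trajectories.

    An epoch is *convergent* when the maximum |dV/dt| (finite differences on
    the sampled trace) over the final ``settle_window_ms`` of its release
    phase stays below ``threshold``.  Final voltages of convergent epochs
    are clustered by single linkage at ``tolerance``; cluster means are the
    loci, indexed in ascending voltage order.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    if not trajectories:
        raise InvalidParameterError("empty trajectory ensemble")

    finals, commands, stats = [], [], []
    for traj in trajectories:
        for ep in range(traj.n_epochs):
            sl = traj.release_slices[ep]
            t, v = traj.time_ms[sl], traj.voltage_mv[sl]
            if t[-1] - t[0] < settle_window_ms:
                raise InvalidParameterError(
                    f"epoch {ep}: release phase shorter than settle window "
                    f"({t[-1] - t[0]:.1f} < {settle_window_ms} ms)"
                )
            in_window = t >= t[-1] - settle_window_ms
            tw, vw = t[in_window], v[in_window]
            dvdt = np.gradient(vw, tw)
            max_rate = float(np.max(np.abs(dvdt)))
            converged = max_rate < threshold
            stats.append({
                "command_mv": traj.commands[ep],
                "final_mv": float(v[-1]),
                "max_dvdt_mv_per_ms": max_rate,
                "converged": converged,
            })
            commands.append(traj.commands[ep])
            finals.append(float(v[-1]) if converged else None)

    conv_vals = np.array([f for f in finals if f is not None])
    if len(conv_vals):
        labels, centers = _single_linkage_1d(conv_vals, tolerance)
        # reindex loci in ascending voltage order
        order = np.argsort(centers)
        remap = {int(old): int(new) for new, old in enumerate(order)}
        centers = [centers[i] for i in order]
    else:
        labels, centers, remap = np.empty(0, int), [], {}

    basin: dict[float, int | None] = {}
    ci = 0
    for cmd, fv in zip(commands, finals):
        if fv is None:
            basin[cmd] = None
        else:
            basin[cmd] = remap[int(labels[ci])]
            ci += 1

    return AttractorReport(loci=centers, basin_map=basin, settle_stats=stats,
                           cluster_tol_mv=tolerance)


def phase_portrait(phase_field: PhaseField,
                   v_range: tuple[float, float] | None = None,
                   grid_step: float = 1.0) -> PhasePortrait:
    """Root scan of a reduced field: sign changes refined by bisection.

    Stability is read from the sign of f' at each root (central difference):
    negative slope = stable, positive = unstable.  Grid-resolved tangential
    zeros (|f| dipping to ~0 without a sign change) are reported half-stable
    and excluded from the memory count.
    """
    if grid_step <= 0:
        raise InvalidParameterError("grid_step must be positive")
    lo, hi = v_range if v_range is not None else phase_field.v_range
    n = int(np.ceil((hi - lo) / grid_step)) + 1
    grid = np.linspace(lo, hi, n)
    vals = np.asarray(phase_field(grid), float)

    roots: list[Root] = []

    def slope_at(v_star: float) -> float:
        h = max(grid_step * 1e-3, 1e-6)
        return float((phase_field(v_star + h) - phase_field(v_star - h)) / (2 * h))

    scale = float(np.max(np.abs(vals))) or 1.0
    i = 0
    while i < len(grid) - 1:
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            v_star = float(grid[i])
            s = slope_at(v_star)
            stab = "stable" if s < 0 else ("unstable" if s > 0 else "half-stable")
            roots.append(Root(v_star, stab))
        elif a * b < 0:
            v_star = float(brentq(lambda v: float(phase_field(v)), grid[i], grid[i + 1],
                                  xtol=ROOT_TOL_MV))
            s = slope_at(v_star)
            roots.append(Root(v_star, "stable" if s < 0 else "unstable"))
        else:
            # tangential zero: interior minimum of |f| at ~0 without sign change
            if 0 < i and abs(a) < 1e-9 * scale and abs(a) <= abs(vals[i - 1]) and abs(a) <= abs(b):
                roots.append(Root(float(grid[i]), "half-stable"))
        i += 1
    if vals[-1] == 0.0:
        s = slope_at(float(grid[-1]))
        roots.append(Root(float(grid[-1]),
                          "stable" if s < 0 else ("unstable" if s > 0 else "half-stable")))

    # deduplicate roots closer than the refinement tolerance
    deduped: list[Root] = []
    for r in sorted(roots, key=lambda r: r.voltage):
        if deduped and abs(r.voltage - deduped[-1].voltage) < 10 * ROOT_TOL_MV:
            continue
        deduped.append(r)
    return PhasePortrait(grid=grid, values=vals, roots=deduped)


def _flow_predicted_attractor(portrait: PhasePortrait, v: float) -> float | None:
    """Attractor a purely 1-D (all-fast) flow reaches from ``v``.

    The nearby attractor in the direction of the reduced flow: the first
    root above ``v`` when f(v) > 0, the first below when f(v) < 0 (for
    transversal alternating roots that adjacent root is stable).  A release
    voltage sitting exactly on a root resolves toward the lower-voltage
    stable root.
    """
    roots = sorted(portrait.roots, key=lambda r: r.voltage)
    stable = [r.voltage for r in roots if r.stability == "stable"]
    if not stable:
        return None
    fv = float(np.interp(v, portrait.grid, portrait.values))
    on_root = [r for r in roots if abs(r.voltage - v) < 1e-6]
    if on_root:
        if on_root[0].stability == "stable":
            return on_root[0].voltage
        below = [s for s in stable if s < v]
        return below[-1] if below else stable[0]
    if fv > 0:
        above = [r for r in roots if r.voltage > v]
        cand = above[0].voltage if above else None
    else:
        below = [r for r in roots if r.voltage < v]
        cand = below[-1].voltage if below else None
    if cand is None:
        # flow leaves the scanned range; fall back to the nearest stable root
        return min(stable, key=lambda r: (abs(r - v), r))
    nearest_stable = min(stable, key=lambda r: (abs(r - cand), r))
    return nearest_stable


def basin_map_consistency(report: AttractorReport,
                          portrait: PhasePortrait) -> list[dict]:
    """Epochs whose attained attractor is not the nearby flow-predicted root.

    The prediction is the attractor the reduced one-dimensional flow would
    reach from the release voltage; a one-dimensional flow cannot pass
    through a fixed point, so for a model whose gates are all fast this list
    is empty.  A mismatch is an *overshoot* event — a slow variable carried
    the trajectory past the nearby attractor — reported with the release
    (command) voltage, the predicted root and the attractor attained.
    """
    if not portrait.stable_roots:
        return []
    events = []
    for cmd, locus_idx in report.basin_map.items():
        if locus_idx is None:
            continue
        attained = report.loci[locus_idx]
        predicted = _flow_predicted_attractor(portrait, cmd)
        if predicted is None:
            continue
        if abs(attained - predicted) > max(report.cluster_tol_mv, 1.0):
            events.append({
                "command_mv": cmd,
                "nearest_root_mv": predicted,
                "attained_mv": attained,
            })
    return events


def classify(report: AttractorReport) -> str:
    """Label a report: monostable / bistable / multistable-n / non-convergent.

    Any unsettled epoch makes the whole report non-convergent — stability by
    simulation requires *every* sampled initial condition to settle.
    """
    if not report.settle_stats:
        raise InvalidParameterError("empty report")
    if report.n_nonconvergent > 0:
        return "non-convergent"
    n = len(report.loci)
    if n == 1:
        return "monostable"
    if n == 2:
        return "bistable"
    return f"multistable-{n}"
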