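# Methods

## Model

A single, space-clamped membrane patch carries an ohmic leak plus a set of
voltage-gated channels:

    -C dV/dt = I_ext + Σ_i ḡ_i · Π_g x_g^{a_g} · (V − E_i) + ḡ_leak (V − E_leak)
    τ_x(V) dx/dt = x_∞(V) − x                      for every gate x

Internal units are fixed: mV, ms, mS/cm², μF/cm² (current densities in
μA/cm²); all inputs are converted on ingestion. In these units
`dV/dt = −I/C` is directly in mV/ms.

Assumptions: single-ion ohmic driving forces (no GHK rectification), fixed
bath and cytoplasmic concentrations (no calcium depletion or pumps), no
second-messenger coupling, and first-order gate kinetics — channels whose
gating is not first-order (e.g. Kv1.5-like) are out of scope, and the
ChannelML reader rejects anything it cannot represent exactly rather than
approximating it.

### Reversal potentials

`E = (RT/zF)·ln([out]/[in])` with R = 8.314 J/(mol·K), F = 96485 C/mol,
0 °C = 273.15 K. The two packaged presets (amphibian oocyte at 23 °C,
mammalian at 36 °C) store concentration pairs, not voltages; reversals are
computed at full precision and rounded only for display. Under these
constants the amphibian preset yields −19 (Na⁺), −156 (K⁺), +45 (Cl⁻) and
−12 mV (Ca⁺⁺) to the nearest mV, and the mammalian preset +60 (Na⁺) and
−67 mV (Cl⁻); the mammalian K⁺ value is −89.70 mV, which rounds to −90.
The mixed Na⁺+K⁺ reversal used by HCN-family channels has no single-ion
Nernst form and is a fixed per-preset constant (−78 mV amphibian, −15 mV
mammalian). The ohmic leak adopts the preset's chloride reversal by
default; both the leak reversal and any channel reversal can be overridden,
which is how the exactly-as-printed model variant (E_Na = 60, E_leak = −67)
is assembled when integer-tabulated reversals are wanted.

### Membrane constants

C = 1 μF/cm² and ḡ_leak = 0.2 mS/cm² by default, giving
τ_membrane = C/ḡ_leak = 5 ms. (The time constant of an RC membrane is
capacitance over conductance; the package computes it as such.) Non-leak
channels default to ḡ = 2 mS/cm² — the 10:1 overexpression ratio — and the
ratio is a parameter of every screen.

### Temperature

Gate timescales measured at a channel's experiment temperature are rescaled
to the preset temperature by `τ → τ · Q10^((T_exp − T_target)/10)` with
Q10 = 3 (overridable per channel). Steady-state curves are not rescaled.

### Fast/slow classification and reduction

The transition window of a gate is the voltage pair where `x_∞` crosses
0.05 and 0.95 (closed-form logit inversion for sigmoids, bracketed
root-finding otherwise). A gate is *fast* when its rescaled τ at **both
window endpoints** falls below τ_membrane. The endpoint rule is the
deliberate default even though a τ peak strictly inside the window can
exceed τ_membrane; an optional strict mode checks the maximum over the
window instead. When all gates are fast, `reduce_fast` substitutes
`x = x_∞(V)` to obtain the scalar field f(V). A slow gate makes the
reduction refuse by name; forcing it yields a field marked approximate —
its roots are still the exact equilibria of the full system (equilibria do
not depend on timescales), but transients and basins are not captured.

## Protocols and integration

An epoch clamps at a command voltage and then releases; the clamp is a
finite ohmic conductance (default 1000 mS/cm², giving sub-0.02 mV clamp
error for the fixture models — `clamp_fidelity` quantifies this) rather
than an ideal source, with an ideal-clamp mode for testing. State carries
continuously across epochs, so a protocol is one continuous simulation; a
reset-per-epoch mode exists but is not the default. The standard screen is
the 30-epoch descending sweep over [−140, 150] mV in 10 mV steps, 50 ms
clamp + 950 ms release; the standard switching demonstration is the
sequence −140, −70, 0, −100, −30 mV at 200 ms clamp + 500 ms release
(3.5 s total). Before the first epoch the state is V at the first command
with gates at steady state there, so the first epoch plays the same role as
every later one.

Integration uses SciPy's LSODA (adaptive, stiff-capable) with rtol 1e-8,
atol 1e-10 and dense output sampled every 0.1 ms. These settings are chosen
for refinement stability — halving the tolerances moves final epoch
voltages by far less than 0.01 mV on the fixture models — not to match any
external numerics. The pipeline contains no randomness; identical inputs
reproduce trajectories bit-for-bit.

## Attractor detection and phase portraits

An epoch is **convergent** when max |dV/dt| (finite differences on the
sampled trace) over the final 100 ms of its release stays below
1e-4 mV/ms. When any epoch of a screen fails this, the screen retries with
the relaxation extended to a 10 s horizon; what has not settled by then is
non-convergent, and a single non-convergent epoch makes the whole model
non-convergent (the conservative reading of "all initial conditions must
settle"). Convergent final voltages are clustered by single linkage at
1 mV; cluster means are the loci, reported at full precision and also
rounded to the nearest mV for tabulation.

The phase portrait scans f(V) at a 1 mV grid step, refines each sign
change by bisection to 1e-6 mV, and labels roots by the sign of f′:
negative = stable, positive = unstable. Grid-resolved tangential zeros are
reported half-stable and excluded from the memory count (they are not
attractors under perturbation).

**Overshoot diagnostics.** For an all-fast model the 1-D flow cannot cross
a fixed point, so each release voltage must reach the attractor the reduced
flow points at (the first root in the direction of sign f — note this is
*not* always the nearest attractor by voltage distance, which the flow can
legitimately be on the far side of an unstable root from).
`basin_map_consistency` reports epochs that violate this prediction: such
overshoot events occur exactly when slow gates carry the trajectory past a
nearby attractor, producing disconnected basins of attraction. A release
voltage sitting exactly on a root resolves toward the lower-voltage stable
root, for determinism.

## Combinatorial screens and memory maximization

Screens enumerate unordered channel subsets at requested arities (X + leak,
X + Y + leak, optionally with a mandatory anchor channel excluded from the
free slots), in deterministic lexicographic order of channel ids, so reruns
and pool permutations give identical tables. Each combination is swept,
classified and tabulated; per-combination failures are recorded as rows,
not fatal. `maximize_memories` — the question argmax_ḡ |r(f(V, ḡ))| — uses
a deterministic linear grid over the conductance box (reproducibility over
speed; the problem statement fixes no algorithm), counts stable roots of
the reduced field at each grid point, and breaks ties toward the smallest
total conductance. It refuses channel sets with slow gates, for which the
root count is not the memory count.

## Fixtures and synthetic data

Shipped channel fixtures (ChannelML-subset XML, same schema the reader
accepts from users):

* `nav16_reduced` — persistent sodium channel: one fast activation gate,
  Boltzmann steady state with half-activation −17 mV and steepness
  0.1565 /mV, constant τ = 1 ms. The 1 ms value is a representative fast
  timescale (well under τ_membrane at both preset temperatures); the
  reduced field does not depend on it.
* `kir_synthetic` — a *synthetic* steep inward-rectifier-like K⁺ channel
  (decreasing sigmoid, half-point −80 mV, steepness 0.15 /mV, τ = 1 ms),
  used for amphibian bistability demonstrations. It is not a database
  Kir2.1 parameterization.
* `slow_inward_synthetic` — a *synthetic* slow (τ = 200 ms)
  hyperpolarization-activated Na-conducting channel engineered so that,
  after release from a −140 mV clamp, its lingering inward current carries
  the voltage past the hyperpolarized attractor — the canonical overshoot /
  disconnected-basin demonstration.

The synthetic channel generator draws unspecified parameters from a seeded
generator within realistic ranges (half-activation −80…20 mV, steepness
0.05…0.3 /mV, τ 0.5…50 ms) and is deterministic given (spec, seed). What
these synthetics emulate is the *shape* class of real channel kinetics
(monotone Boltzmann activation/inactivation, first-order relaxation); they
do not emulate multi-gate cooperativity, non-first-order kinetics, true
rectification of the open-channel I–V, or measured parameter values of any
named channel. Tests passing on them validate the machinery — assembly,
reduction, integration, detection, screening — not the biological
membership of any published channel table, which would require the original
database parameter sets.

## Numerical choices and degenerate inputs

* Root refinement: Brent bisection, xtol 1e-6 mV; roots closer than
  1e-5 mV are merged.
* Clustering: single linkage on a line = split sorted finals at gaps
  > 1 mV.
* exp-linear rate law: the removable singularity at V = midpoint is
  evaluated by its limit.
* Sigmoid saturation: at |V| ≳ 250/k the curve saturates to float 0/1;
  monotonicity is strict only on the transition region.
* Degenerate protocols: a zero-span sweep yields a single epoch; an empty
  clamp sequence, non-divisible sweep grid, non-positive durations or
  conductances are rejected with explicit errors.

## Known limitations

Fixed points only: oscillatory attractors are flagged non-convergent, never
characterized. Single cell only: no gap-junction coupling, no membrane
subdomains. The screen validates machinery on fixtures and synthetics; the
published channel-by-channel screen membership is not desk-reproducible
without the external kinetic parameter sets, and is not claimed. Problem
sizes used throughout (30-epoch sweeps of 1 s epochs, 50-model synthetic
ensembles, 21-point conductance grids) are the package's standard
demonstration scales and run in seconds to a few minutes on one core.
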