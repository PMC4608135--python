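# voltmem

Conductance-based simulation and phase-portrait analysis of **multistable
resting membrane potentials** in non-spiking cells.

Most cells are not neurons, yet their resting potential V_mem is an
instructive signal in development, regeneration and cancer. Because ion
channels are both gated by and help set V_mem, a cell expressing the right
channel mix can hold more than one stable resting voltage — a rewritable
bioelectric memory that a transient voltage clamp can flip, like a flip-flop.
`voltmem` builds Hodgkin–Huxley-type membrane models from parameterized
channel kinetics, simulates clamp/release protocols, and detects and
characterizes these voltage memories under amphibian-oocyte (23 °C) and
mammalian (36 °C) ionic conditions.

## The model

The membrane obeys the standard current-balance ODE

```
-C dV/dt = I_ext + Σ_i ḡ_i m_i^a h_i^b (V − E_i) + ḡ_leak (V − E_leak)
```

with gating variables relaxing as `τ_x(V) dx/dt = x_∞(V) − x`, where
`x_∞` is a Boltzmann sigmoid on [0, 1] and `τ_x` is positive (constant,
Gaussian-bell, or derived from α/β rates). Reversal potentials `E_i` come
from the Nernst equation applied to packaged ionic-condition tables;
timescales are recalibrated across temperatures with Q10 = 3.

When every gate relaxes faster than the membrane RC time
`τ_membrane = C/ḡ_leak` (5 ms at the defaults C = 1 μF/cm²,
ḡ_leak = 0.2 mS/cm²), the substitution `x ≈ x_∞(V)` collapses the system to
a scalar field `dV/dt = f(V)`. Roots of `f` are resting potentials, stable
where `f'(V) < 0`; the number of stable roots `|r(f)|` is the number of
voltage memories. The package provides both routes — stiff ODE simulation
of clamp sweeps and direct root/stability analysis of the reduced field —
and cross-checks them against each other.

## Worked example

The reduced persistent sodium channel (Boltzmann activation, half-activation
−17 mV, steepness 0.1565 /mV) paired with an ohmic leak at a 10:1
conductance ratio (2 vs 0.2 mS/cm²):

```python
import voltmem as vm

cond  = vm.load_conditions("mammalian")          # Na 15/145, K 145/5, Cl 10/125 mM, 36 degC
model = vm.build_model([vm.load_channel("nav16_reduced")], cond)

portrait = vm.phase_portrait(vm.reduce_fast(model))
print([(round(r.voltage, 1), r.stability) for r in portrait.roots])
# [(-66.8, 'stable'), (-39.8, 'unstable'), (48.8, 'stable')]

traj   = vm.simulate(model, vm.make_sweep_protocol())   # 30 epochs, 150 -> -140 mV
report = vm.detect_attractors(traj)
print(vm.classify(report), report.loci_rounded)
# bistable [-67, 49]
```

Two attractors: a hyperpolarized memory near the leak (chloride) reversal,
where the sodium channels are closed, and a depolarized memory near the
sodium reversal, where they are open and overwhelm the leak. Every one of
the 30 clamped initial voltages settles onto one of these two loci, matching
the phase-portrait roots to better than 0.5 mV. Under amphibian-oocyte
gradients the reversal ordering inverts (E_Na = −19 mV *below*
E_leak = +45 mV) and the same channel pair is monostable:

```python
amph = vm.build_model([vm.load_channel("nav16_reduced")], vm.load_conditions("amphibian"))
print(vm.phase_portrait(vm.reduce_fast(amph)).memory_count)   # 1
```

The same analyses are available from the shell:

```bash
voltmem nernst --ion Na --in 15 --out 145 --z 1 --temp 36     # 60
voltmem portrait --model nav16_leak --conditions mammalian
voltmem sweep    --model nav16_leak --conditions mammalian
voltmem switch   --model nav16_leak --conditions mammalian --sequence -140,-70,0,-100,-30
voltmem search   --conditions amphibian --arity 1
```

The `switch` run drives the bistable cell through a clamp sequence and logs
the attractor attained after each release, demonstrating reversible writing
of the voltage state. See `docs/methods.md` for the numerical details,
fixtures and limitations.

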