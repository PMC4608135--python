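# Standard mammalian cell preparation: chemical gradients at 36 degC.
name: mammalian
temperature_c: 36.0
ions:
  Na: {intracellular_mm: 15.0, extracellular_mm: 145.0, valence: 1}
  K: {intracellular_mm: 145.0, extracellular_mm: 5.0, valence: 1}
  Cl: {intracellular_mm: 10.0, extracellular_mm: 125.0, valence: -1}
fixed_reversals_mv:
  NaK: -15.0
leak_species: Cl
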