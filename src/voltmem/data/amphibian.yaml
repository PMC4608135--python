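# Amphibian (Xenopus) oocyte preparation: chemical gradients at 23 degC.
# The mixed Na+K reversal used by HCN channels is a fixed literature value,
# not computed from concentrations (no single-ion Nernst formula applies).
name: amphibian
temperature_c: 23.0
ions:
  Na: {intracellular_mm: 21.0, extracellular_mm: 10.0, valence: 1}
  K: {intracellular_mm: 90.0, extracellular_mm: 0.2, valence: 1}
  Cl: {intracellular_mm: 60.0, extracellular_mm: 10.4, valence: -1}
  Ca: {intracellular_mm: 0.5, extracellular_mm: 0.2, valence: 2}
fixed_reversals_mv:
  NaK: -78.0
leak_species: Cl
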