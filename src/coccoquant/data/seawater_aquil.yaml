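# Artificial seawater culture medium (Aquil-style), 10 mM CaCl2.
# Mass fractions per chemical species; expanded to elemental weight
# fractions at load time and renormalized to sum to 1.
name: seawater_aquil
density: 1.025
components:
  H2O: 0.96689
  Na: 0.01078
  Mg: 0.00128
  Ca: 0.00040
  K: 0.00040
  Cl: 0.01935
  S: 0.00090
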