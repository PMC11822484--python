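"""Physical constants (SI)."""

#: Boltzmann constant [J/K] (CODATA 2018, exact by definition).
K_B = 1.380649e-23
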