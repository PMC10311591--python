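"""Physical constants shared across modules."""

#: gas constant, J mol^-1 K^-1
R_J = 8.314

#: gas constant, kJ mol^-1 K^-1 (free energies are carried in kJ/mol)
R_KJ = R_J / 1000.0

#: default simulation/analysis temperature, K
T_DEFAULT = 300.0
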