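# Acetabular cup, reference parameter set, torsional removal (mode III).
# Coarse default mesh; raise `n` and `bone_layers` for refined runs.
scenario: aci
mode: III
law: mc
phi0: 1.0
E_b: 0.2 GPa
IF: 1 mm
mu_b: 0.3
a_s: 128 um
b_s: 1.84
t0: 1.8 MPa
n_removal: 50
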