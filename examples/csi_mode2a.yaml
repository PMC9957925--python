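# Coin-shaped implant, mode IIa: tangential sliding under constant -70 N
# compression, fully osseointegrated interface, modified Coulomb law.
scenario: csi
test: IIa
law: mc
phi0: 1.0
a_s: 22 um
b_s: 0.74
mu_ub: 0.44
mu_b: 0.3
du: 0.65 um
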