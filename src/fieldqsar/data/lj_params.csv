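element,epsilon_kcal_mol,sigma_A
H,0.030,2.50
C,0.066,3.50
N,0.170,3.25
O,0.210,2.96
F,0.061,2.94
S,0.250,3.55
Cl,0.300,3.40
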