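symbol,Z,atomic_mass,radius_pm,ref_density
H,1,1.008,,
C,6,12.011,,2.266
N,7,14.007,,
O,8,15.999,140,
Na,11,22.990,102,
Mg,12,24.305,72,
P,15,30.974,38,
S,16,32.06,184,
Cl,17,35.45,181,
K,19,39.098,138,
Ca,20,40.078,100,
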