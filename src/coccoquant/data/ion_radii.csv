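species,formula,radius_pm
Ca,Ca,100
Mg,Mg,72
Na,Na,102
K,K,138
Cl,Cl,181
PO3,PO3,200
PO4,PO4,238
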