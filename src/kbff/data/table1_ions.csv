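species,sigma_nm,epsilon_kjmol,charge_e,mass_u
K,0.283,0.90,1,39.0983
Na,0.231,0.45,1,22.98977
Cl,0.43,0.42,-1,35.45
Br,0.443,0.75,-1,79.90
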