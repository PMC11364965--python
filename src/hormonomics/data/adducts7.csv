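label,kind,delta,terms
M+H-2H2O,adduct,-35.013304,+1*1*H -1*2*H2O
M+H-H2O,adduct,-17.002740,+1*1*H -1*1*H2O
M+NH4-H2O,adduct,0.023809,+1*1*NH4 -1*1*H2O
M+Li,adduct,7.016005,+1*1*Li
M+NH4,adduct,18.034374,+1*1*NH4
M+CH3OH-H,adduct,31.018390,+1*1*CH3OH -1*1*H
M+K,adduct,38.963707,+1*1*K
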