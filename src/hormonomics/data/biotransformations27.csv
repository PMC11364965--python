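label,kind,delta,terms
M+CH3,biotransformation,15.023475,+1*1*CH3
M+C6H12O6,biotransformation,180.063388,+1*1*C6H12O6
M+OH,biotransformation,17.002740,+1*1*OH
M+COOH,biotransformation,44.997654,+1*1*COOH
M+NH2,biotransformation,16.018724,+1*1*NH2
M+NH3,biotransformation,17.026549,+1*1*NH3
M-H+OH,biotransformation,15.994915,-1*1*H +1*1*OH
M-H+2OH,biotransformation,32.997654,-1*1*H +1*2*OH
M-H+NH2,biotransformation,15.010899,-1*1*H +1*1*NH2
M-CH3+H,biotransformation,-14.015650,-1*1*CH3 +1*1*H
M-CH3+OH,biotransformation,1.979265,-1*1*CH3 +1*1*OH
M-CH3+NH2,biotransformation,0.995249,-1*1*CH3 +1*1*NH2
M-C6H12O6+H,biotransformation,-179.055563,-1*1*C6H12O6 +1*1*H
M-C6H12O6+OH,biotransformation,-163.060648,-1*1*C6H12O6 +1*1*OH
M-C6H12O6+NH2,biotransformation,-164.044664,-1*1*C6H12O6 +1*1*NH2
M-C6H12O6+CH3,biotransformation,-165.039913,-1*1*C6H12O6 +1*1*CH3
M-OH+H2,biotransformation,-14.987090,-1*1*OH +1*1*H2
M-OH+CH3,biotransformation,-1.979265,-1*1*OH +1*1*CH3
M-OH+C6H12O6,biotransformation,163.060648,-1*1*OH +1*1*C6H12O6
M-OH+COOH,biotransformation,27.994915,-1*1*OH +1*1*COOH
M-OH+NH2,biotransformation,-0.984016,-1*1*OH +1*1*NH2
M-OH+NH3,biotransformation,0.023809,-1*1*OH +1*1*NH3
M-NH2+H2,biotransformation,-14.003074,-1*1*NH2 +1*1*H2
M-NH2+CH3,biotransformation,-0.995249,-1*1*NH2 +1*1*CH3
M-NH2+C6H12O6,biotransformation,164.044664,-1*1*NH2 +1*1*C6H12O6
M-NH2+COOH,biotransformation,28.978930,-1*1*NH2 +1*1*COOH
M-NH2+OH,biotransformation,0.984016,-1*1*NH2 +1*1*OH
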