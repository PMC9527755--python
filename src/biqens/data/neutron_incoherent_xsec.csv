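# Bound-atom incoherent neutron scattering cross sections, natural abundance
# unless an isotope is named. Values in barn, from the standard tabulation of
# neutron scattering lengths and cross sections (Sears, Neutron News 3 (1992) 26).
# version: 1
element,sigma_inc_barn
H,80.26
D,2.05
C,0.001
N,0.50
O,0.0008
S,0.007
P,0.005
Se,0.32
Fe,0.40
Zn,0.077
Na,1.62
Cl,5.3
Mg,0.08
Ca,0.05
K,0.27
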