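# graphpka element property registry, version 1
# electronegativity: Pauling scale
# hardness: absolute (Pearson) chemical hardness, eV
# covalent_radius: single-bond covalent radius, Angstrom (atomic diameter = 2x)
symbol,atomic_number,electronegativity,hardness,covalent_radius
H,1,2.20,6.43,0.31
B,5,2.04,4.01,0.84
C,6,2.55,5.00,0.76
N,7,3.04,7.23,0.71
O,8,3.44,6.08,0.66
F,9,3.98,7.01,0.57
Si,14,1.90,3.38,1.11
P,15,2.19,4.88,1.07
S,16,2.58,4.14,1.05
Cl,17,3.16,4.68,1.02
Se,34,2.55,3.87,1.20
Br,35,2.96,4.22,1.20
I,53,2.66,3.69,1.39
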