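# Per-residue hydropathy scales.
# eisenberg: Eisenberg normalised consensus scale (Eisenberg et al. 1984,
#   J Mol Biol 179:125-142) - used for GRAVY.
# kyte_doolittle: Kyte & Doolittle (1982, J Mol Biol 157:105-132) - used,
#   rescaled to [0,1] by (h+4.5)/9, for charge-hydropathy plot coordinates.
residue	eisenberg	kyte_doolittle
A	0.62	1.8
R	-2.53	-4.5
N	-0.78	-3.5
D	-0.90	-3.5
C	0.29	2.5
Q	-0.85	-3.5
E	-0.74	-3.5
G	0.48	-0.4
H	-0.40	-3.2
I	1.38	4.5
L	1.06	3.8
K	-1.50	-3.9
M	0.64	1.9
F	1.19	2.8
P	0.12	-1.6
S	-0.18	-0.8
T	-0.05	-0.7
W	0.81	-0.9
Y	0.26	-1.3
V	1.08	4.2
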