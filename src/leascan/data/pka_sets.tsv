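# pKa tables for Henderson-Hasselbalch net-charge and pI calculation.
# emboss: defaults of the EMBOSS iep program.
# sillero: Sillero & Ribeiro (1989, Anal Biochem 179:319-325).
# Groups: Nterm/Cterm are the free termini; single letters are side chains.
group	emboss	sillero
Nterm	8.6	8.2
Cterm	3.6	3.2
C	8.5	9.0
D	3.9	4.0
E	4.1	4.5
H	6.5	6.4
K	10.8	10.4
R	12.5	12.0
Y	10.1	10.0
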