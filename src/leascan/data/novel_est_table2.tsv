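# Published physicochemical parameters of the 12 novel (database-match-free)
# dehydration-induced A. avenae ESTs: predicted protein length, pI, GRAVY
# (Eisenberg consensus scale) and percent disorder. Used as a standing
# regression input for the hydrophilic/disordered screening rule
# (GRAVY < -0.43 or disorder > 50%), which flags 6 of the 12.
accession	n_amino_acids	pi	gravy	percent_disorder
GR463919	179	9.28	-1.16	75
GR463920	98	10.51	-0.87	39
GR463921	88	4.36	0.01	78
GR463922	168	11.13	-0.55	39
GR463923	144	6.78	0.20	16
GR463924	35	6.69	-0.13	37
GR463925	143	9.82	-0.08	22
GR463926	140	9.64	-0.97	51
GR463927	122	10.91	-0.30	37
GR463928	37	6.33	0.28	46
GR463929	59	4.17	0.99	0
EF026246	61	6.35	-2.32	20
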