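# Spliced-leader catalogue: the 12 leader sequences observed at the 5' ends
# of A. avenae mRNAs plus the two canonical C. elegans leaders used as family
# references. "Variant 8" is stored without the leading alignment gap of the
# published table (its observed leader is the 21-mer shown here).
# family: SL1 | SL2 | unassigned (variant leaders are assigned at run time by
# global alignment against the canonical leaders).
name	sequence	family	organism
SL1a	GGTTTATATACCCAAGTTTGAG	SL1	Aphelenchus avenae
SL1b	GGTTTTATTACCCAAGTTTGAG	SL1	Aphelenchus avenae
SL1c	GGTTTAAATACCCAAATTTGAG	SL1	Aphelenchus avenae
SL1d	GGTTTAAATACCCTAATTTGAG	SL1	Aphelenchus avenae
Variant1	GGTTTAAATACCCTTTATTGAG	unassigned	Aphelenchus avenae
Variant2	GGTTTATACACCCAAGTTTGAG	unassigned	Aphelenchus avenae
Variant3	GGTTTTATTACCCCAGTTTGAG	unassigned	Aphelenchus avenae
Variant4	GGTTTAAATACCCGAATTTGAG	unassigned	Aphelenchus avenae
Variant5	GGTTTACACCCAGTATCACAAG	unassigned	Aphelenchus avenae
Variant6	GGTTTAATACCCAGTATCACAAG	unassigned	Aphelenchus avenae
Variant7	GGTTTAAAACCCAGTATCACAAG	unassigned	Aphelenchus avenae
Variant8	GTTTTTACAGAAAACCACAAG	unassigned	Aphelenchus avenae
SL1	GGTTTAATTACCCAAGTTTGAG	SL1	Caenorhabditis elegans
SL2	GGTTTTAACCCAGTTACTCAAG	SL2	Caenorhabditis elegans
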