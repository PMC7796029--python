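Name	Seq	Length	Tm	Product	Orientation	Role	Target
P16sf	AAGGGCCGCGGTAACTCTG	19	61.7	414	forward	universal	-
S16sr	ACCCTGTTATCCCCGTGGT	19	59.5	414	reverse	universal	-
CA16sr	ACCTGCTACTCCCTAAGGTTTAAATTTAGTG	31	58	226	reverse	species_specific	Chironex Sp.A
CI16sr	ACCTACTGTTCCCTAGAGTTTAAGTTTAAAGG	32	57.6	226	reverse	species_specific	Chironex indrasaksajiae
CC16sr	CCTCTAAAGTATCTAATCTAAAGTGGAGGGTAG	33	57	217	reverse	species_specific	Chironex Sp.C
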