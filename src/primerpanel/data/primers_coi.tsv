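Name	Seq	Length	Tm	Product	Orientation	Role	Target
jgLCO1490	TNTCNACNAAYCAYAARGAYATTGG	25	56	709	forward	universal	-
jgHCO2198	TANACYTCNGGRTGNCCRAARAAYCA	26	60	709	reverse	universal	-
CAcof	CACCGCTTTTTCCATGTTGATTAGATTAGAAT	32	57.7	535	forward	species_specific	Chironex Sp.A
Chironex_cor	CATCGTTATAGCRCCTGCTARCACAGGYART	31	62.8		reverse	universal	-
CIcof	CTGTGTACCCTCCCCTATCAGCCATTCAATC	31	62.8	245	forward	species_specific	Chironex indrasaksajiae
CCcof	GGCATTCCCAAGACTAAACAACATATCCTTC	31	59.1	349	forward	species_specific	Chironex Sp.C
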