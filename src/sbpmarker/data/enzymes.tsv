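name	site	cut_top	cut_bottom	warning
TaqI	TCGA	1	3
RsaI	GTAC	2	2
Tsp509I	AATT	0	4
DdeI	CTNAG	1	4
AccI	GTMKAC	2	4
MspI	CCGG	1	3
BamHI	GGATCC	1	5
NheI	GCTAGC	1	5
DpnI	GATC	2	2	Dam-methylation requirement ignored: treated as an unconditional GATC cutter
Hpy166II	GTNNAC	3	3
BtsCI	GGATG	7	5
MboII	GAAGA	13	12
HphI	GGTGA	13	12
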