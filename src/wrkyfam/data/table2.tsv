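species	Cre	Ppa	Smo	Pab	Ath	Dca	Vvi	Mdo	Osa
Cre	1
Ppa	0/0	67
Smo	2/2	8/37	6
Pab	0/0	7/26	7/12	237
Ath	0/0	6/12	8/7	11/5	26
Dca	0/0	8/25	10/14	10/12	28/23	56
Vvi	0/0	5/12	7/5	15/40	31/16	36/38	7
Mdo	0/0	4/29	12/22	14/29	34/52	46/97	48/72	102
Osa	0/0	2/5	8/11	8/7	18/8	21/19	19/11	19/29	41
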