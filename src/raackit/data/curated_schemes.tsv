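type	size	clusters	source
t0	20	A-C-D-E-F-G-H-I-K-L-M-N-P-Q-R-S-T-V-W-Y	identity alphabet (no reduction)
t1	2	LVIMCAGSTPFYW-EDNQKRH	Murphy et al. 2000, BLOSUM50-based clustering
t1	4	LVIMC-AGSTP-FYW-EDNQKRH	Murphy et al. 2000, BLOSUM50-based clustering
t1	8	LVIMC-AG-ST-P-FYW-EDNQ-KR-H	Murphy et al. 2000, BLOSUM50-based clustering
t1	10	LVIM-C-A-G-ST-P-FYW-EDNQ-KR-H	Murphy et al. 2000, BLOSUM50-based clustering
t1	15	LVIM-C-A-G-S-T-P-FY-W-E-D-N-Q-KR-H	Murphy et al. 2000, BLOSUM50-based clustering
t2	5	CMFILVWY-ATH-GP-DE-SNQRK	Wang and Wang 1999, interaction (MJ) matrix minimal alphabet
t3	2	CMFILVWY-AGTSNQDEHRKP	hydrophobic-polar (HP) model
t4	6	AGPST-C-DENQ-FWY-HKR-ILMV	Dayhoff-style physico-chemical groups
t5	4	ADKERNTSQ-YFLIVMCWH-G-P	GBMR4, structure-derived grouping
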