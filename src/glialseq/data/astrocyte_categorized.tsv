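symbol	category	log2fc	adj_p
RCAN2	acute_injury	0.4	0.0091
Lrrc58	acute_injury	0.31	0.0036
ARL4C	acute_injury	0.3	0.0029
PRELP	acute_injury	0.27	0.0368
YWHAZ	acute_injury	0.26	0.0014
DNTTIP2	acute_injury	0.24	0.0244
CDC42SE1	acute_injury	0.23	0.0082
HINT1	acute_injury	0.22	0.004
CARS	acute_injury	0.22	0.0079
IARS	acute_injury	0.21	0.0097
ARNTL	acute_injury	0.19	0.024
LRRC41	acute_injury	0.19	0.0461
SSBP3	acute_injury	0.19	0.0202
BRCC3	acute_injury	0.19	0.0288
LRRC59	acute_injury	0.18	0.0391
UBE2F	acute_injury	0.18	0.0219
FARSB	acute_injury	0.16	0.0366
CNBP	acute_injury	0.14	0.0482
SGPL1	acute_injury	-0.2	0.0388
AXL	acute_injury	-0.21	0.0334
LAP3	acute_injury	-0.21	0.0321
SGCB	acute_injury	-0.21	0.0213
RNF141	acute_injury	-0.27	0.0039
SYNE1	acute_injury	-0.3	0.0102
POLD4	acute_injury	-0.34	0.0375
PLIN2	acute_injury	-0.38	0.0084
IL33	acute_injury	-0.91	0.0001
IGSF1	acute_injury	-0.92	0.0057
UCP2	pan_injury	1.2	0.0088
ATF3	pan_injury	0.94	0.0077
GPNMB	pan_injury	0.79	0.0039
LGALS3	pan_injury	0.67	0.0282
ARHGDIB	pan_injury	0.54	0.0103
RHOJ	pan_injury	0.46	0.0117
PARP3	pan_injury	0.45	0.0065
TIMP3	pan_injury	0.38	0.0216
AHNAK	pan_injury	0.33	0.0173
PPARGC1A	pan_injury	0.26	0.0276
ELOVL2	pan_injury	0.25	0.0113
MCL1	pan_injury	0.21	0.016
AHCYL1	pan_injury	0.16	0.0148
B2M	pan_injury	-0.17	0.0416
DST	pan_injury	-0.21	0.028
SQLE	pan_injury	-0.27	0.0246
APLN	pan_injury	-0.28	0.0433
PTPRD	pan_injury	-0.33	0.0006
FLOT1	pan_injury	-0.33	0.0116
NSDHL	pan_injury	-0.35	0.0137
HMGCS1	pan_injury	-0.43	0.0002
CTSS	pan_injury	-0.51	0.0005
VIM	pan_injury	-0.51	1.91e-05
IDI1	pan_injury	-0.55	0.0009
IFIT3	pan_injury	-0.75	0.036
S1PR1	chronic_neurodegenerative	-0.33	0.0006
ARSK	chronic_neurodegenerative	-0.33	0.0089
COBL	chronic_neurodegenerative	-0.47	0.0172
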