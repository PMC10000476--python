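symbol	category	log2fc	adj_p
PTPRN	OPC	1.03	0.0011
GNG3	OPC	0.27	0.0053
PRKCB	OPC	-0.17	0.039
LNX1	OPC	-0.37	0.0017
SERPINA3N	OPC	0.98	0.012
DSCAM	OPC	0.27	0.0173
DNM3	OPC	-0.18	0.0334
RSU1	OPC	-0.4	0.0007
SMOX	OPC	0.9	0.0001
NMNAT2	OPC	0.26	0.013
DISP2	OPC	-0.18	0.0349
JAM2	OPC	-0.41	0.0006
GPNMB	OPC	0.79	0.0039
CXADR	OPC	0.25	0.0102
DDAH1	OPC	-0.2	0.0476
PHLDB1	OPC	-0.42	0.0004
SORCS1	OPC	0.6	0.0003
ABHD17B	OPC	0.25	0.0113
PCDH9	OPC	-0.22	0.0174
LBH	OPC	-0.44	0.0002
MIDN	OPC	0.42	0.0088
SCG5	OPC	0.25	0.0033
PCDH10	OPC	-0.23	0.0301
RAMP1	OPC	-0.45	0.0003
TRIL	OPC	0.39	0.0116
CHPT1	OPC	0.24	0.011
OMG	OPC	-0.23	0.0191
EDNRB	OPC	-0.47	0.0027
HIP1	OPC	0.35	0.0003
PHACTR3	OPC	0.24	0.0278
SLC35F1	OPC	-0.24	0.0275
COBL	OPC	-0.47	0.0172
KANK1	OPC	0.33	0.016
EHD3	OPC	0.23	0.0139
SLC22A15	OPC	-0.24	0.0188
GLTP	OPC	-0.48	0.0006
ITGAV	OPC	0.33	0.0034
DLGAP1	OPC	0.2	0.0124
PCDH17	OPC	-0.25	0.0235
GJC3	OPC	-0.48	0.0001
CALY	OPC	0.32	0.0021
ADORA1	OPC	0.2	0.0151
ADCYAP1R1	OPC	-0.25	0.0029
PTN	OPC	-0.52	0.0002
GPT2	OPC	0.31	0.0014
ZCCHC24	OPC	0.2	0.0245
SVIL	OPC	-0.26	0.0391
PLXNB3	OPC	-0.52	0.0105
CASKIN2	OPC	0.31	0.0163
PTPRE	OPC	0.2	0.0168
KLHL5	OPC	-0.27	0.0075
MMP15	OPC	-0.56	0.0239
KCNK3	OPC	0.3	0.013
RAB31	OPC	0.19	0.0231
GRIA4	OPC	-0.29	0.0018
RCN1	OPC	-0.65	0.0103
NCALD	OPC	0.3	0.0041
NELL2	OPC	0.19	0.0125
SERINC5	OPC	-0.3	0.0016
RLBP1	OPC	-0.78	0.0021
LRRFIP1	OPC	0.29	0.0024
GNPTG	OPC	0.18	0.0202
KLHL13	OPC	-0.31	0.0113
EMID1	OPC	-0.84	0.0013
CAV2	OPC	0.28	0.0473
GAD1	OPC	0.15	0.0246
CSPG5	OPC	-0.34	0.0086
PLLP	OPC	-1.11	0.0001
SDC3	OPC	0.28	0.0411
NOVA1	OPC	-0.16	0.0402
GNB4	OPC	-0.35	0.0008
TIMP4	COP	0.42	0.0001
SEZ6L	COP	0.4	0.0005
SIRT2	COP	-0.16	0.0479
SLC44A1	COP	-0.18	0.046
EDIL3	COP	-0.2	0.0247
S100B	COP	-0.24	0.008
BCAS1	COP	-0.28	0.0412
CNP	COP	-0.3	0.0066
GPR17	COP	-0.33	0.0116
EPB41L2	COP	-0.35	0.0016
LIMS2	COP	-0.38	0.0468
ENPP6	COP	-0.53	0.0036
H2-AB1	NFOL	-1.38	0.0007
SEMA4D	NFOL	-0.16	0.0484
APOD	MFOL	1.66	0.0001
LAP3	MFOL	-0.21	0.0321
SEPTIN4	MFOL	-0.35	0.0005
UGT8A	MFOL	-1.16	0.002
HSPA1A	MFOL	0.92	0.0054
ATP8A1	MFOL	-0.21	0.0091
ERMN	MFOL	-0.37	0.0346
SERPINB1A	MFOL	-1.28	3.22e-05
ADIPOR2	MFOL	0.9	0.0018
SCCPDH	MFOL	-0.21	0.0377
MAG	MFOL	-0.39	0.0346
OPALIN	MFOL	-2.33	6.07e-07
GLUL	MFOL	0.79	0.001
FGFR2	MFOL	-0.21	0.0362
QDPR	MFOL	-0.41	0.0029
PIM3	MFOL	0.64	0.0005
FNBP1	MFOL	-0.21	0.0116
PHLDB1	MFOL	-0.42	0.0004
KLF13	MFOL	0.53	0.0001
CCP110	MFOL	-0.22	0.0142
MAP6D1	MFOL	-0.43	0.0002
HAPLN2	MFOL	0.42	0.0267
DIP2A	MFOL	-0.22	0.0113
CRYAB	MFOL	-0.43	0.0445
TUBB4A	MFOL	0.41	0.0036
PCDH9	MFOL	-0.22	0.0174
ABCA8A	MFOL	-0.46	0.0122
FTH1	MFOL	0.39	0.0054
TPST1	MFOL	-0.23	0.0279
GNG11	MFOL	-0.46	0.0049
KNDC1	MFOL	0.39	0.0335
DOCK10	MFOL	-0.23	0.035
NIPA1	MFOL	-0.47	0.0001
SLC38A2	MFOL	0.34	0.0003
CNTN2	MFOL	-0.23	0.0218
GLTP	MFOL	-0.48	0.0006
SLC20A2	MFOL	0.3	0.0013
TULP4	MFOL	-0.23	0.0022
GPR37	MFOL	-0.48	0.0005
CFL2	MFOL	0.28	0.004
OMG	MFOL	-0.23	0.0191
GJC3	MFOL	-0.48	0.0001
ZDHHC20	MFOL	0.24	0.0249
EPS15	MFOL	-0.24	0.0189
CAR2	MFOL	-0.5	0.001
NUDT4	MFOL	0.24	0.0047
ARAP2	MFOL	-0.24	0.013
PRR5L	MFOL	-0.5	0.0043
LPGAT1	MFOL	0.21	0.0097
AATK	MFOL	-0.25	0.0321
ANO4	MFOL	-0.5	0.001
PAK1	MFOL	0.21	0.0071
SEMA6D	MFOL	-0.25	0.0062
ARSG	MFOL	-0.52	0.0029
TMOD2	MFOL	0.2	0.016
KCNA6	MFOL	-0.27	0.0047
PLXNB3	MFOL	-0.52	0.0105
GPX4	MFOL	0.2	0.0175
GATM	MFOL	-0.27	0.0091
1700047M11RIK	MFOL	-0.53	0.0012
PSAT1	MFOL	0.19	0.0409
BCAS1	MFOL	-0.28	0.0412
LPAR1	MFOL	-0.54	0.0012
PCNP	MFOL	0.18	0.0231
S1PR5	MFOL	-0.29	0.0214
TMEM88B	MFOL	-0.56	0.0002
CDC37L1	MFOL	0.16	0.0424
GRM3	MFOL	-0.29	0.0346
CMTM5	MFOL	-0.59	0.0017
ATP6AP2	MFOL	0.16	0.0309
EPHB1	MFOL	-0.29	0.0059
FA2H	MFOL	-0.67	0.0004
DENND5A	MFOL	-0.16	0.0239
UNC5B	MFOL	-0.29	0.0226
ASPA	MFOL	-0.67	0.0001
ACOT7	MFOL	-0.17	0.0496
TMEFF1	MFOL	-0.3	0.0304
HHIP	MFOL	-0.73	0.0033
MYO6	MFOL	-0.17	0.0271
SERINC5	MFOL	-0.3	0.0016
TMEM125	MFOL	-0.75	0.0102
SLC44A1	MFOL	-0.18	0.046
CNP	MFOL	-0.3	0.0066
SOX2OT	MFOL	-0.85	0.0052
SORT1	MFOL	-0.18	0.0127
TTYH2	MFOL	-0.31	0.0053
PPP1R14A	MFOL	-0.86	0.0011
DNM3	MFOL	-0.18	0.0334
TPPP	MFOL	-0.32	0.0026
MOG	MFOL	-0.86	0.001
ANK3	MFOL	-0.19	0.013
TRIM59	MFOL	-0.33	0.0334
PDLIM2	MFOL	-0.87	0.0014
YPEL2	MFOL	-0.2	0.041
REEP3	MFOL	-0.33	0.0022
IL33	MFOL	-0.91	0.0001
EDIL3	MFOL	-0.2	0.0247
PTPRD	MFOL	-0.33	0.0006
PRR18	MFOL	-0.91	0.0003
KCNJ10	MFOL	-0.2	0.0348
PACS2	MFOL	-0.34	0.0008
PLP1	MFOL	-1.07	5.01e-07
WNK1	MFOL	-0.2	0.0039
DPY19L1	MFOL	-0.34	0.0012
PLLP	MFOL	-1.11	0.0001
DST	MFOL	-0.21	0.028
TSPAN2	MFOL	-0.35	0.0008
GJC2	MFOL	-1.11	0.0043
NINJ2	MOL	-1.88	0.0005
KLK6	MOL	-1.04	0.0016
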