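symbol	log2fc	adj_p
FOSB	2.81	0.0081
IFRD1	0.65	0.0001
SLC25A5	0.27	0.001
CMTM6	-0.21	0.0438
PIK3CD	-0.5	0.0057
GPX3	2.68	1.77e-09
ZFP36	0.62	0.0027
CCNL1	0.27	0.0035
MKNK1	-0.22	0.0422
CTSS	-0.51	0.0005
CCL2	2.44	0.0015
KLF4	0.6	0.0238
FTL1	0.26	0.0021
EDEM2	-0.23	0.0235
PLD4	-0.52	0.0208
CDKN1A	2.31	0.0007
ANXA3	0.58	0.0021
TMSB4X	0.26	0.0037
DOCK10	-0.23	0.035
KCTD12	-0.53	1.79e-05
FCNA	2.06	0.0028
ARHGDIB	0.54	0.0103
PTBP1	0.23	0.0289
RGS3	-0.23	0.0465
IFI203	-0.54	0.0313
MAFF	1.94	0.0002
IER3	0.5	0.0012
MYLIP	0.23	0.0321
TLN2	-0.24	0.0188
COL27A1	-0.54	0.0433
CCL7	1.81	0.0025
IER2	0.5	0.0318
BRD2	0.23	0.0038
SLC38A6	-0.24	0.0467
HPGDS	-0.6	0.01
C5AR1	1.53	0.0044
PROS1	0.48	0.0116
KLF6	0.23	0.0368
PLXDC2	-0.24	0.0134
UNC93B1	-0.6	0.0014
GM3002	1.4	0.0405
ICAM1	0.46	0.0449
MCL1	0.21	0.016
RGL2	-0.25	0.0089
TREM2	-0.62	0.017
MSR1	1.34	0.0221
CFH	0.45	0.0092
PCF11	0.21	0.0071
PPCDC	-0.25	0.0401
ITGAM	-0.65	0.001
EVI2B	1.25	0.0051
LAIR1	0.45	0.0055
CLTC	0.21	0.007
SLC29A3	-0.25	0.0314
CCR5	-0.67	0.0274
LYVE1	1.22	0.0164
DUSP6	0.44	0.007
CYFIP1	0.2	0.0136
ZFP90	-0.25	0.0257
SELPLG	-0.67	0.0003
UCP2	1.2	0.0088
REL	0.44	0.0343
ZCCHC2	0.2	0.0245
SLCO2B1	-0.28	0.0484
DSN1	-0.68	0.0116
CSRNP1	1.1	8.39e-06
RGS2	0.43	0.0281
FMNL1	0.19	0.0425
CAMK1	-0.28	0.004
IRF7	-0.7	0.0273
APOC1	1.05	0.0009
TSPO	0.42	0.0433
SERINC3	0.19	0.0467
GPR155	-0.28	0.013
APOBEC1	-0.7	0.0296
SPP1	1.05	0.0315
ZFP36L2	0.41	0.0021
IL16	0.18	0.0149
TLR3	-0.3	0.0436
HK2	-0.77	0.0023
MERTK	1	0.0348
CD300A	0.41	0.0117
ARPC2	0.17	0.0203
AKR1B10	-0.3	0.01
IFI27L2A	-0.77	0.0403
F13A1	0.98	0.0109
SAT1	0.41	0.0007
PCNA	0.17	0.035
UBC	-0.31	0.0056
FGD2	-0.83	0.0048
SERPINB8	0.97	0.0282
1700017B05RIK	0.4	0.0163
UBE2J1	0.17	0.0384
AGO4	-0.32	0.0367
LY86	-0.84	0.0002
KLF10	0.95	0.0022
COTL1	0.39	0.0018
ELMO1	0.16	0.022
APH1C	-0.35	0.0282
FCRLS	-0.85	0.0032
ATF3	0.94	0.0077
ATF4	0.39	0.0003
SEMA4D	-0.16	0.0484
EPB41L2	-0.35	0.0016
HPGD	-0.87	0.0004
HSPA1A	0.92	0.0054
SRGN	0.37	0.0237
ASAH1	-0.17	0.0333
LPCAT2	-0.35	0.0344
KLHL6	-0.95	0.0173
ARHGAP27	0.83	0.0001
ISYNA1	0.35	0.0247
B2M	-0.17	0.0416
ARHGAP11A	-0.37	0.0465
SIGLECH	-0.98	0.0005
SOCS3	0.81	0.0258
H3F3B	0.33	0.0072
LY6E	-0.19	0.0276
HEXB	-0.38	0.0003
OAS2	-0.98	0.0095
GPNMB	0.79	0.0039
PPP1R15A	0.31	0.0263
TPP1	-0.19	0.0097
CSF1R	-0.42	0.002
P2RY12	-1.1	0.0001
PHYHD1	0.78	1.08e-05
ARL4C	0.3	0.0029
SGPL1	-0.2	0.0388
MPEG1	-0.42	0.0088
CD74	-1.18	0.0001
CD68	0.73	0.0096
CCDC9	0.29	0.0047
IL6ST	-0.2	0.0219
GPR34	-0.43	0.0433
H2-AA	-1.55	0.0029
EGR1	0.72	0.0028
HERPUD1	0.28	0.0076
PMP22	-0.2	0.0479
CRYL1	-0.44	0.013
SPARC	0.71	2.21e-08
SKI	0.28	0.0104
RRBP1	-0.2	0.0274
SALL1	-0.45	0.0173
C3AR1	0.69	0.0154
SERPINF1	0.28	0.0375
AXL	-0.21	0.0334
RENBP	-0.46	0.0219
SH2B2	0.68	0.0052
PTPRJ	0.27	0.006
COMMD8	-0.21	0.044
P2RY13	-0.48	0.0356
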