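symbol	category	log2fc	adj_p
MERTK	homeostatic	1	0.0348
EGR1	homeostatic	0.72	0.0028
SLCO2B1	homeostatic	-0.28	0.0484
HEXB	homeostatic	-0.38	0.0003
CSF1R	homeostatic	-0.42	0.002
GPR34	homeostatic	-0.43	0.0433
SALL1	homeostatic	-0.45	0.0173
P2RY13	homeostatic	-0.48	0.0356
KCTD12	homeostatic	-0.53	1.79e-05
Hpgds	homeostatic	-0.6	0.01
CCR5	homeostatic	-0.67	0.0274
FGD2	homeostatic	-0.83	0.0048
FCRLS	homeostatic	-0.85	0.0032
Siglech	homeostatic	-0.98	0.0005
P2RY12	homeostatic	-1.1	0.0001
GPX3	neurodegenerative	2.68	1.77e-09
CCL2	neurodegenerative	2.44	0.0015
MSR1	neurodegenerative	1.34	0.0221
SPP1	neurodegenerative	1.05	0.0315
GPNMB	neurodegenerative	0.79	0.0039
CD68	neurodegenerative	0.73	0.0096
LAIR1	neurodegenerative	0.45	0.0055
TREM2	neurodegenerative	-0.62	0.017
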