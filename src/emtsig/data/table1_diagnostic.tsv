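gene	direction	p_value
ABCA12	up	6.03e-05
ARTN	up	1.62e-12
CD24	up	1.62e-12
CDH1	up	9.56e-08
CDH2	up	3.45e-08
CKMT1A	up	<1e-12
CKMT1B	up	1.62e-12
CLDN3	up	<1e-12
CLDN4	up	2.92e-08
CLDN7	up	1.62e-12
COL1A1	up	1.62e-12
COL1A2	up	1.62e-12
COL3A1	up	<1e-12
COL5A1	up	1.62e-12
COL5A2	up	1.62e-12
COL6A1	up	<1e-12
CORO1A	up	1.62e-12
DSP	up	6.9e-10
ECM1	up	1.62e-12
EPCAM	up	1.62e-12
ERBB3	up	<1e-12
ESR1	up	<1e-12
ESRP1	up	<1e-12
ESRP2	up	1.62e-12
FN1	up	<1e-12
FXYD3	up	1.62e-12
GREM1	up	2.09e-09
GRHL2	up	1.62e-12
ITGA5	up	2.42e-04
ITGBL1	up	3.33e-16
KRT18	up	1.62e-12
LAD1	up	1.62e-12
LRRC1	up	1.11e-16
MAL2	up	1.62e-12
MGAT5B	up	1.11e-16
MLPH	up	1.62e-12
MMP3	up	<1e-12
MMP9	up	2.09e-05
MST1R	up	<1e-12
OCLN	up	1.62e-12
PKP3	up	1.62e-12
PLIN3	up	<1e-12
PLP2	up	1.62e-12
POSTN	up	1.62e-12
RAB25	up	<1e-12
S100A14	up	<1e-12
SAMD9	up	<1e-12
SERPINE1	up	8.56e-11
SPINT2	up	1.62e-12
SPRR1B	up	1.26e-03
ST14	up	<1e-12
SYK	up	2.6e-06
TCF3	up	1.62e-12
TGFB1	up	1.62e-12
THY1	up	1.62e-12
TSPAN1	up	1.62e-12
VCAN	up	<1e-12
ABCC4	down	1.06e-03
ABLIM1	down	1.62e-12
ACSL4	down	1.62e-12
ADAM9	down	1.27e-08
ALDH1A1	down	<1e-12
ALDH1A3	down	1.62e-12
ANXA8	down	3.67e-06
AXL	down	3.33e-16
CD44	down	9.79e-05
CDH3	down	1.10e-03
COL17A1	down	<1e-12
DCBLD2	down	<1e-12
DCN	down	1.62e-12
DNAJB4	down	1.62e-12
EGFR	down	2.22e-16
ELK3	down	1.11e-16
FBLN5	down	1.62e-12
FGFBP1	down	2.13e-05
GJB3	down	9.02e-11
GNG11	down	<1e-12
IL1B	down	3.04e-03
IL4R	down	1.00e-09
ITGA6	down	<1e-12
ITGB1	down	1.39e-13
JAG1	down	3.33e-16
KLF10	down	<1e-12
KLK5	down	2.34e-08
KRT14	down	1.62e-12
KRT15	down	<1e-12
KRT16	down	8.79e-08
KRT17	down	5.55e-16
KRT5	down	<1e-12
LAMA3	down	1.62e-12
LIFR	down	<1e-12
MCAM	down	<1e-12
NR2F1	down	7.51e-09
NRP1	down	<1e-12
PMP22	down	1.11e-16
PRKCH	down	<1e-12
PRRX1	down	4e-02
PTX3	down	1.81e-08
RGL1	down	<1e-12
S100A2	down	2.82e-03
S100A8	down	1.31e-06
SAA1	down	5.55e-16
SEMA5A	down	1.62e-12
SERPINB2	down	1.03e-04
SNAI2	down	1.74e-12
SOX10	down	<1e-12
TBX3	down	5.36e-04
TFPI	down	<1e-12
TGFB1I1	down	<1e-12
THBD	down	1.62e-12
TP63	down	<1e-12
TWIST1	down	7.72e-12
TWIST2	down	<1e-12
VIM	down	1.62e-12
WNT5A	down	1.8e-02
ZEB1	down	1.62e-12
ZEB2	down	<1e-12
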