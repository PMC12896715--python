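gene	direction	p_dmfs	p_os	p_rfs
ABCA12	worse	3e-04	8e-04	7.9e-03
ADAM9	worse	1.3e-07	3.8e-05	4.6e-13
ARTN	worse	7.5e-03	3.8e-02	3.1e-03
CD24	worse	1.4e-07	9.2e-07	4e-12
CDH2	worse	1.2e-04	8.3e-06	4.2e-07
CKMT1A	worse	2.1e-16	3.6e-08	7.8e-14
CKMT1B	worse	2.1e-16	3.6e-08	7.8e-14
CLDN1	worse	9.7e-05	2.1e-02	4.5e-05
CLDN3	worse	2e-02	7.4e-04	6.4e-05
CLDN4	worse	9.5e-03	3e-03	1.2e-02
CLDN7	worse	5.3e-06	2.1e-04	7.3e-03
EPCAM	worse	4.5e-06	2.1e-04	<1e-16
ESRP1	worse	3.9e-07	3.7e-05	8e-14
ESRP2	worse	5.4e-04	4.5e-05	3.4e-04
FN1	worse	9.7e-04	2.9e-02	5e-03
GREM1	worse	4.6e-07	2.4e-03	5.6e-11
ITGB1	worse	1e-03	5.5e-03	1.1e-09
KRT16	worse	9.8e-09	1.5e-05	9e-15
LAD1	worse	4.4e-11	2.4e-04	1.4e-08
LAMA3	worse	4.9e-02	1.8e-02	7.1e-03
LTBP1	worse	2e-07	1.4e-02	1.6e-06
MGAT5B	worse	1.2e-02	1.2e-02	2.1e-05
MT2A	worse	3.8e-05	8.2e-05	8.5e-07
NDRG1	worse	4.6e-11	3.4e-07	<1e-16
PLP2	worse	2.7e-04	8e-03	3e-11
S100A8	worse	6.9e-09	6.8e-06	1.3e-12
SERPINE1	worse	4.1e-03	2.5e-02	1.7e-05
SLPI	worse	1.4e-06	4.5e-04	8.3e-06
SNAI1	worse	1.8e-07	1.6e-04	7.4e-04
ST14	worse	1.6e-05	1.5e-06	4.6e-09
TCF3	worse	1.5e-04	1.8e-03	6.6e-06
TGFB1	worse	3.6e-02	4.6e-02	1.6e-02
THY1	worse	1.8e-03	5.4e-03	3.7e-03
ALDH1A1	better	1.1e-06	5e-08	8.2e-10
AXL	better	3.8e-02	1.4e-02	1.3e-04
CD44	better	3.6e-08	7.9e-05	3e-13
CDH1	better	3.2e-02	4e-02	3.5e-06
COL17A1	better	2.5e-03	7.8e-04	8e-16
COL6A1	better	3.3e-02	3.6e-03	1.1e-04
CORO1A	better	1.7e-03	3.1e-04	2.3e-03
DCN	better	8.7e-05	3.4e-03	1.7e-04
ERBB3	better	2.6e-03	5.8e-04	7.9e-05
ESR1	better	<1e-16	2.2e-07	<1e-16
FBLN5	better	1.1e-02	5.3e-04	5.9e-07
FGFR2	better	1.8e-11	1.2e-08	3.1e-11
FST	better	4.4e-02	1.8e-02	5e-07
ITGBL1	better	7.6e-03	5.2e-03	4e-07
KCNMA1	better	8.2e-05	4.5e-05	1.7e-08
KRT14	better	1.2e-04	2.8e-03	6.8e-07
LIFR	better	4.4e-04	5.3e-08	4.5e-09
MLPH	better	2.2e-08	3.9e-03	<1e-16
NR2F1	better	2.2e-02	1.6e-02	4.2e-02
PLAT	better	5.9e-10	2.1e-04	1.1e-11
PRKCH	better	1.4e-03	8.3e-03	1.6e-09
S100A14	better	2.9e-02	6e-03	6.2e-03
SAA1	better	1.8e-05	4.2e-03	6.6e-05
SEMA5A	better	1.9e-02	1.3e-02	5.6e-06
SERPINB1	better	1.5e-04	1.4e-03	<1e-16
TBX3	better	1.8e-04	5.7e-04	3.1e-10
TFPI	better	4.3e-02	5.5e-05	5.4e-03
TP63	better	3.7e-02	2.4e-03	3.5e-10
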