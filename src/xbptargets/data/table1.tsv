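gene	n_motifs	induced_xbp1s	tg_vs_ctrl	tg_sixbp1_vs_ctrl	tg_sixbp1_vs_tg	tm_vs_ctrl	tm_sixbp1_vs_ctrl	tm_sixbp1_vs_tm
ACLY	1	1.15	0.80*	0.61*	0.77*	0.77*	0.85*	1.09
ANK2	1	1.45*	2.75*	4.30*	1.56	3.09*	5.53*	1.79
ATF3	6	1.09	2.30*	4.74*	2.06*	7.69*	6.53*	0.85
BBC3	4	0.51*	2.14*	3.85*	1.80*	1.89*	4.05*	2.15*
CALR	14	1.19	1.95*	1.83*	0.94	1.50*	1.56*	1.04
CDK6	5	1.17	0.84*	0.48*	0.57*	1.25	0.82*	0.65
CDKN1A	10	1.18	1.00	2.87*	2.86*	1.05	2.77*	2.65*
CHAC1	1	1.36*	8.84*	9.17*	1.04	14.85*	10.84*	0.73
DDIT3	0	1.02	8.78*	12.38*	1.41*	19.00*	13.14*	0.69*
CLIP2	12	1.13	1.01	1.72*	1.71	0.92	2.25*	2.43*
DHCR24	2	1.39	1.08	1.15	1.07	1.01	1.45*	1.44*
DNAJA1	4	1.13	0.72*	0.59*	0.82	0.72	0.86*	1.19
DNAJB2	4	0.96	1.41	1.62	1.15	1.18	1.81*	1.53*
DNAJB9	3	1.67*	6.36*	4.18*	0.66*	6.00*	2.81*	0.47*
DSP	2	1.33	0.70	0.78	1.11	1.04	1.22*	1.18
DUSP5	12	1.08	1.08	1.26	1.16	1.23	1.46*	1.19
DUSP6	4	1.52	1.13	1.34	1.18	1.21	2.16*	1.78*
EDEM1	7	1.71*	2.64*	1.90*	0.72*	2.24*	1.18*	0.53*
EGR1	1	1.09	1.18	0.55*	0.47*	5.10*	1.19	0.23*
ERLEC1	6	1.70*	1.01	0.94	0.93	1.04	1.06	1.01
ERN1	4	0.56*	1.86*	3.57*	1.92*	1.83*	2.92*	1.60*
FOXJ2	4	1.59*	0.80	0.75*	0.93	0.91	0.79	0.86
GADD45A	2	1.08	1.53	2.27*	1.48*	3.26*	3.62*	1.11
GADD45B	2	1.12	1.29	1.05	0.82	2.29*	2.11*	0.92
HSPA1B	13	0.63*	1.03	1.47	1.42	0.93	1.08	1.16
HSPA5	11	1.10	6.46*	4.26*	0.66*	4.18*	2.59*	0.62*
HSPA6	5	0.13	0.38	0.61	1.61	0.17*	0.51	2.96
HSPA8	1	1.29	0.57*	0.52*	0.91	0.53*	0.67*	1.26
ICAM1	4	1.06	1.97*	3.02*	1.53	1.24	3.12*	2.52*
IL1A	3	1.21	2.59*	5.91*	2.28	2.97*	3.95*	1.33*
IL6	4	1.37	2.30*	3.04*	1.32*	1.57*	2.00*	1.28*
MAP3K7CL	4	0.95	2.13*	2.32*	1.09	2.34*	2.26*	0.96
NFKB2	11	1.32	1.40	1.69*	1.20	1.18	1.85*	1.56*
RCAN1	6	1.13	2.28*	5.38*	2.36*	1.34*	2.02*	1.51*
SEC23B	3	1.36*	1.32*	1.07	0.81*	3.27	1.24	0.38
SNAI1	5	1.51*	1.08	1.27	1.17	1.22	1.17	0.96
TRIB3	5	1.10	3.79*	3.79*	1.00	2.34*	2.61*	1.12
WARS	3	1.58*	1.54	1.83*	1.19*	1.44	1.64*	1.14
GADD34	14	0.27*	1.43*	2.37*	1.65*	3.05*	2.37*	0.78*
ZNF432	3	1.01	1.08	1.09	1.01	1.12	1.44	1.29
XBP1s		8.73	10.60	2.20	0.21	15.21	1.46	0.10
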