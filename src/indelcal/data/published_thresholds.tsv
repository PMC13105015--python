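tool	variant_type	direction	level	interval_low	interval_high	low_inclusive	high_inclusive
CADD	deletion	higher_pathogenic	-3	-inf	0.878	False	True
CADD	deletion	higher_pathogenic	-2	0.878	9.81	False	True
CADD	deletion	higher_pathogenic	-1	9.81	14.91	False	True
CADD	deletion	higher_pathogenic	1	21.9	inf	True	False
FATHMM-indel	deletion	higher_pathogenic	-4	-inf	0.048	False	True
FATHMM-indel	deletion	higher_pathogenic	-3	0.048	0.127	False	True
FATHMM-indel	deletion	higher_pathogenic	-2	0.127	0.365	False	True
FATHMM-indel	deletion	higher_pathogenic	-1	0.365	0.675	False	True
FATHMM-indel	deletion	higher_pathogenic	1	0.961	0.982	True	False
FATHMM-indel	deletion	higher_pathogenic	2	0.982	inf	True	False
INDELpred	deletion	higher_pathogenic	-4	-inf	0.023	False	True
INDELpred	deletion	higher_pathogenic	-3	0.023	0.037	False	True
INDELpred	deletion	higher_pathogenic	-2	0.037	0.090	False	True
INDELpred	deletion	higher_pathogenic	-1	0.090	0.153	False	True
INDELpred	deletion	higher_pathogenic	1	0.781	inf	True	False
MutPred-Indel	deletion	higher_pathogenic	-2	-inf	0.165	False	True
MutPred-Indel	deletion	higher_pathogenic	-1	0.165	0.221	False	True
MutPred-Indel	deletion	higher_pathogenic	1	0.659	0.779	True	False
MutPred-Indel	deletion	higher_pathogenic	2	0.779	0.834	True	False
MutPred-Indel	deletion	higher_pathogenic	3	0.834	inf	True	False
VEST-Indel	deletion	higher_pathogenic	-3	-inf	0.16	False	True
VEST-Indel	deletion	higher_pathogenic	-2	0.16	0.35	False	True
VEST-Indel	deletion	higher_pathogenic	-1	0.35	0.40	False	True
VEST-Indel	deletion	higher_pathogenic	1	0.83	0.92	True	False
VEST-Indel	deletion	higher_pathogenic	2	0.92	0.98	True	False
VEST-Indel	deletion	higher_pathogenic	3	0.98	inf	True	False
ESM1b	deletion	lower_pathogenic	1	-8.55	-3.45	False	True
ESM1b	deletion	lower_pathogenic	2	-12.79	-8.55	False	True
ESM1b	deletion	lower_pathogenic	3	-inf	-12.79	False	True
ProGen2	deletion	lower_pathogenic	-1	0.0	inf	True	False
ProGen2	deletion	lower_pathogenic	1	-0.052	-0.030	False	True
ProGen2	deletion	lower_pathogenic	2	-0.129	-0.052	False	True
ProGen2	deletion	lower_pathogenic	3	-inf	-0.129	False	True
PROVEAN	deletion	lower_pathogenic	-4	-0.28	inf	True	False
PROVEAN	deletion	lower_pathogenic	-3	-0.53	-0.28	True	False
PROVEAN	deletion	lower_pathogenic	-2	-2.29	-0.53	True	False
PROVEAN	deletion	lower_pathogenic	-1	-4.80	-2.29	True	False
PROVEAN	deletion	lower_pathogenic	1	-19.82	-9.10	False	True
PROVEAN	deletion	lower_pathogenic	2	-23.07	-19.82	False	True
PROVEAN	deletion	lower_pathogenic	3	-inf	-23.07	False	True
CADD	insertion	higher_pathogenic	-1	-inf	4.72	False	True
CADD	insertion	higher_pathogenic	1	20.3	34.0	True	False
CADD	insertion	higher_pathogenic	2	34.0	inf	True	False
FATHMM-indel	insertion	higher_pathogenic	-1	-inf	0.008	False	True
FATHMM-indel	insertion	higher_pathogenic	1	0.845	inf	True	False
INDELpred	insertion	higher_pathogenic	-4	-inf	0.008	False	True
INDELpred	insertion	higher_pathogenic	-3	0.008	0.010	False	True
INDELpred	insertion	higher_pathogenic	-2	0.010	0.054	False	True
INDELpred	insertion	higher_pathogenic	-1	0.054	0.127	False	True
MutPred-Indel	insertion	higher_pathogenic	-1	-inf	0.212	False	True
MutPred-Indel	insertion	higher_pathogenic	1	0.691	0.838	True	False
MutPred-Indel	insertion	higher_pathogenic	2	0.838	inf	True	False
VEST-Indel	insertion	higher_pathogenic	-1	-inf	0.21	False	True
VEST-Indel	insertion	higher_pathogenic	1	0.80	0.91	True	False
VEST-Indel	insertion	higher_pathogenic	2	0.91	1.0	True	False
VEST-Indel	insertion	higher_pathogenic	3	1.0	inf	True	False
ESM1b	insertion	lower_pathogenic	1	-7.52	-4.25	False	True
ESM1b	insertion	lower_pathogenic	2	-inf	-7.52	False	True
ProGen2	insertion	lower_pathogenic	1	-0.076	-0.037	False	True
ProGen2	insertion	lower_pathogenic	2	-inf	-0.076	False	True
PROVEAN	insertion	lower_pathogenic	-2	0.64	inf	True	False
PROVEAN	insertion	lower_pathogenic	-1	-1.19	0.64	True	False
PROVEAN	insertion	lower_pathogenic	1	-8.17	-6.69	False	True
PROVEAN	insertion	lower_pathogenic	2	-inf	-8.17	False	True
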