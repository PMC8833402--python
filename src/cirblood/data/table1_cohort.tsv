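sample_id	patient_id	timepoint	sex	age	grade_initial	grade_rert	dose_total	n_fractions	survival_months	event
P01_T0	P01	0	male	52	IV	IV	30	10	9.5	1
P01_T1	P01	1	male	52	IV	IV	30	10	9.5	1
P01_T2	P01	2	male	52	IV	IV	30	10	9.5	1
P01_T3	P01	3	male	52	IV	IV	30	10	9.5	1
P02_T0	P02	0	male	51	IV	IV	33	11	7.2	1
P02_T1	P02	1	male	51	IV	IV	33	11	7.2	1
P02_T2	P02	2	male	51	IV	IV	33	11	7.2	1
P02_T3	P02	3	male	51	IV	IV	33	11	7.2	1
P03_T0	P03	0	male	55	IV	IV	36	12	11.4	1
P03_T1	P03	1	male	55	IV	IV	36	12	11.4	1
P03_T3	P03	3	male	55	IV	IV	36	12	11.4	1
P04_T0	P04	0	female	61	IV	IV	33	11	5.8	1
P04_T1	P04	1	female	61	IV	IV	33	11	5.8	1
P04_T2	P04	2	female	61	IV	IV	33	11	5.8	1
P04_T3	P04	3	female	61	IV	IV	33	11	5.8	1
P05_T0	P05	0	female	53	IV	IV	30	10	13.1	1
P05_T1	P05	1	female	53	IV	IV	30	10	13.1	1
P05_T2	P05	2	female	53	IV	IV	30	10	13.1	1
P05_T3	P05	3	female	53	IV	IV	30	10	13.1	1
P06_T0	P06	0	female	44	IV	IV	33	11	8.4	1
P06_T1	P06	1	female	44	IV	IV	33	11	8.4	1
P06_T2	P06	2	female	44	IV	IV	33	11	8.4	1
P07_T0	P07	0	female	58	IV	IV	30	10	10.2	1
P07_T1	P07	1	female	58	IV	IV	30	10	10.2	1
P07_T2	P07	2	female	58	IV	IV	30	10	10.2	1
P07_T3	P07	3	female	58	IV	IV	30	10	10.2	1
P08_T0	P08	0	male	41	III	III	33	11	24.6	1
P08_T1	P08	1	male	41	III	III	33	11	24.6	1
P08_T2	P08	2	male	41	III	III	33	11	24.6	1
P08_T3	P08	3	male	41	III	III	33	11	24.6	1
P09_T0	P09	0	male	46	III	III	36	12	18.3	0
P09_T1	P09	1	male	46	III	III	36	12	18.3	0
P09_T2	P09	2	male	46	III	III	36	12	18.3	0
P09_T3	P09	3	male	46	III	III	36	12	18.3	0
P10_T0	P10	0	male	38	II	III	30	10	30.5	0
P10_T2	P10	2	male	38	II	III	30	10	30.5	0
P10_T3	P10	3	male	38	II	III	30	10	30.5	0
P11_T0	P11	0	male	43	II	III	33	11	16.9	1
P11_T1	P11	1	male	43	II	III	33	11	16.9	1
P11_T2	P11	2	male	43	II	III	33	11	16.9	1
P11_T3	P11	3	male	43	II	III	33	11	16.9	1
P12_T0	P12	0	male	49	II	III	36	12	21.7	1
P12_T1	P12	1	male	49	II	III	36	12	21.7	1
P12_T2	P12	2	male	49	II	III	36	12	21.7	1
P13_T0	P13	0	male	35	II	IV	30	10	28.4	1
P13_T1	P13	1	male	35	II	IV	30	10	28.4	1
P13_T2	P13	2	male	35	II	IV	30	10	28.4	1
P13_T3	P13	3	male	35	II	IV	30	10	28.4	1
P14_T0	P14	0	female	42	II	IV	33	11	25.1	1
P14_T1	P14	1	female	42	II	IV	33	11	25.1	1
P14_T3	P14	3	female	42	II	IV	33	11	25.1	1
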