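patient_id	age	infertility_years	cycles	gv	mi	pb1	empty_atretic
P01	25	7	3	13	2	16	5
P02	30	5	2	8	1	9	4
P03	27	5	4	16	3	20	6
P04	38	12	1	4	1	4	2
P05	32	5	3	12	2	15	5
P06	34	6	2	8	1	9	4
P07	35	4	5	20	3	25	8
P08	30	4	2	8	2	8	4
P09	30	7	1	7	1	0	3
P10	27	3	3	21	4	0	9
P11	35	8	1	7	1	0	3
P12	33	10	2	14	2	0	6
P13	36	11	1	7	1	0	3
P14	40	2	1	7	1	0	3
P15	24	11	4	32	5	0	10
P16	31	4	2	11	2	5	4
P17	34	8	6	30	6	16	15
P18	35	10	7	50	9	0	20
P19	31	11	3	18	3	7	7
P20	29	3	1	4	1	5	1
P21	26	9	1	7	1	0	3
P22	33	2	2	14	2	0	6
P23	34	8	1	7	1	0	3
P24	32	6	1	7	1	0	3
P25	37	5	4	28	5	0	12
P26	25	10	5	35	6	0	15
P27	26	7	3	21	4	0	9
P28	32	9	1	7	1	0	3
P29	40	7	4	29	5	0	11
P30	34	7	1	7	1	0	3
P31	26	2	2	13	3	0	6
P32	26	13	1	7	1	0	3
P33	30	9	3	22	4	0	8
P34	31	8	1	7	1	0	3
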