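module	n_proteins	n_interactions	median_traffic	n_imi
1	33	87	64	2
2	17	57	32	3
3	21	84	40	12
4	33	84	64	7
5	32	94	62	7
6	37	117	72	4
7	133	731	264	46
8	11	26	20	1
9	100	469	198	31
10	24	64	46	7
11	19	54	36	8
12	51	182	100	8
13	68	212	134	14
14	7	21	12	3
15	18	42	34	4
16	112	390	222	9
17	30	91	58	1
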