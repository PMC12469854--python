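mode	affinity	rmsd_lb	rmsd_ub
1	−7.259	0	0
2	−6.705	22.38	23.67
3	−6.652	22.23	23.29
4	−6.494	3.092	8.357
5	−6.484	15.39	17.38
6	−6.461	15.81	18.06
7	−6.417	15.16	17.87
8	−6.395	14.52	16.83
9	−6.386	18.74	20.63
10	−6.386	16.06	18.75
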