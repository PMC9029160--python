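bicluster	luminal_A	luminal_B	normal_like	basal
1	0.10	0	0.17	0.73
2	0.12	0.29	0.46	0.12
3	0.27	0.12	0.38	0.23
4	0.07	0.36	0.32	0.25
5	0.21	0.25	0.42	0.12
6	0.04	0.46	0.35	0.15
7	0.04	0.40	0.40	0.16
8	0.04	0.42	0.42	0.12
9	0.04	0.42	0.38	0.16
10	0.08	0.24	0.48	0.20
11	0.03	0.37	0.29	0.31
12	0.29	0.14	0.43	0.14
13	0.05	0.33	0.57	0.05
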