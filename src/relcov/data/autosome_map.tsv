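chrom	cM
1	284.9
2	269.3
3	223.3
4	214.6
5	204.1
6	192.0
7	187.2
8	168.0
9	166.4
10	181.1
11	158.2
12	174.7
13	125.9
14	120.8
15	141.9
16	134.0
17	128.5
18	117.5
19	107.9
20	108.3
21	62.8
22	74.1
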