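# caption_2n: 58
# provenance: published ancestral Paenungulata homology matrix (APK rows vs aardvark, elephant, Florida manatee, hyrax, Amazonian manatee and human columns)
APK	OAF	LAF	TML	PCA	TIN	HSA
1	2qhi	3 inv/cr	1	1, 16p?	1 inv	5/21
2	3qcd	2	2	2	3	1/19
3	3p	1q	3	5	5	6
4	1qhi	5, 17	5 inv/cr	4	2 inv/cr	4
5	4q	4	7 inv/cr	3	4 inv/cr	10p/12/22q-dist
6	6qa	6	10	6	6	2q
7	4p	7, 12	4q	7	16	11
8	7q	10	11	8	17	9
9	5p	8	6q	9	15	7
10	5qbc	9	13	11	8	14
11	7p	15	16	12	14	8q
12	8q	18	21	13	18	10q
13	1pbc	20	14	15	13	16q
14	1qa	16	22	17	21	13
15	3qab	21, 22	8q	18	19	1
16	1qc	12	23	19	23	2pq-prox
17	6qbc	14	9p	20	25	7/16p
18	1qe	14	15p	21	9	2pq-prox
19	2qa	19	9q	14	24	3
20	8p	11	20	10, 22	20	17
21	5qa	17	8p	10	22	15
22	2qfg	21	15q	?	9	3/21
23	2q	1p	6p	16	27	3
24	1pa + 6p	13	12	23	7	19q/18
25	1qf + 9q	25	17	25	12	8p/22q-prox
26	2p	23	4p	24q	26	20
27	1qb + 2qd	26	18	26	10	3/13q
28	1qd + 2qb (c)	27 (24)	19	22	11	2pq-prox/3
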