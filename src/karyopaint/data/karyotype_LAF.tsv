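# species_code: LAF
# sex_system: XX/XY
# printed_2n: 56
# provenance: chromosome count from published diploid number; per-chromosome morphology not reported
label	category	morphology
1	autosome	unknown
2	autosome	unknown
3	autosome	unknown
4	autosome	unknown
5	autosome	unknown
6	autosome	unknown
7	autosome	unknown
8	autosome	unknown
9	autosome	unknown
10	autosome	unknown
11	autosome	unknown
12	autosome	unknown
13	autosome	unknown
14	autosome	unknown
15	autosome	unknown
16	autosome	unknown
17	autosome	unknown
18	autosome	unknown
19	autosome	unknown
20	autosome	unknown
21	autosome	unknown
22	autosome	unknown
23	autosome	unknown
24	autosome	unknown
25	autosome	unknown
26	autosome	unknown
27	autosome	unknown
X	X	unknown
Y	Y	unknown
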