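# species_code: TML
# sex_system: XX/XY
# printed_2n: 48
# printed_FN: 92
# provenance: Florida manatee karyotype (23 bi-armed autosome pairs; chromosomes 4, 6, 8 and 9 submetacentric)
label	category	morphology
1	autosome	biarmed
2	autosome	biarmed
3	autosome	biarmed
4	autosome	submetacentric
5	autosome	biarmed
6	autosome	submetacentric
7	autosome	biarmed
8	autosome	submetacentric
9	autosome	submetacentric
10	autosome	biarmed
11	autosome	biarmed
12	autosome	biarmed
13	autosome	biarmed
14	autosome	biarmed
15	autosome	biarmed
16	autosome	biarmed
17	autosome	biarmed
18	autosome	biarmed
19	autosome	biarmed
20	autosome	biarmed
21	autosome	biarmed
22	autosome	biarmed
23	autosome	biarmed
X	X	unknown
Y	Y	unknown
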