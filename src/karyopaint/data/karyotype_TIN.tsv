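# species_code: TIN
# sex_system: XX/XY
# printed_2n: 56
# printed_FN: 92
# provenance: Amazonian manatee karyotype census (19 bi-armed + 8 acrocentric autosome pairs; submetacentric X, acrocentric Y); acrocentric pairs are the split homologs of TML 4, 6, 8 and 9
label	category	morphology
1	autosome	biarmed
2	autosome	biarmed
3	autosome	biarmed
4	autosome	biarmed
5	autosome	biarmed
6	autosome	biarmed
7	autosome	biarmed
8	autosome	biarmed
9	autosome	biarmed
10	autosome	biarmed
11	autosome	biarmed
12	autosome	biarmed
13	autosome	biarmed
14	autosome	biarmed
15	autosome	acrocentric
16	autosome	acrocentric
17	autosome	biarmed
18	autosome	biarmed
19	autosome	acrocentric
20	autosome	biarmed
21	autosome	biarmed
22	autosome	acrocentric
23	autosome	biarmed
24	autosome	acrocentric
25	autosome	acrocentric
26	autosome	acrocentric
27	autosome	acrocentric
X	X	submetacentric
Y	Y	acrocentric
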