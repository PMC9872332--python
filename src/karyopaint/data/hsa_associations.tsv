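# provenance: human-chromosome syntenic associations reported for the Amazonian manatee in the published comparative discussion (ancestral eutherian, Afrotherian and Paenungulata markers)
pair	clade	tin_chromosomes	status
3/21	EAK	9	present
7/16	EAK	25	present
12/22	EAK	4;14	present
14/15	EAK	8	present
16/19	EAK	13	present
5/21	Afrotheria	1	present
2/3	APK	9;12	present
18/19	APK	7	present
8/22	APK	14	present
4/8	EAK		absent
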