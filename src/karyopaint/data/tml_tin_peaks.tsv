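# probe_species: TML
# target_species: TIN
# provenance: whole-chromosome TML flow-peak probes hybridised onto TIN metaphases (published FISH homology table)
probe	targets
1	1
2+4	3;16;26
3+7	4;5
5	2
6+X	15;27;X
8	19;22
9	24;25
10	6
11	17
11+13	8;17
12	7
14	13
15	9
16	14
17	12
18	10
14+19	11;13
20	20
20	20
17+21	12;18
22	21
23	23
Y	Y
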