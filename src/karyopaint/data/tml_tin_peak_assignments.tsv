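# provenance: per-chromosome attribution of composite flow-peak signals, from the published one-to-one probe enumeration
peak	member	targets
2+4	2	3
2+4	4	16;26
3+7	3	5
3+7	7	4
6+X	6	15;27
6+X	X	X
11+13	11	17
11+13	13	8
14+19	14	13
14+19	19	11
17+21	17	12
17+21	21	18
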