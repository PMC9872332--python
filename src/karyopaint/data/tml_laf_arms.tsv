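# probe_species: TML
# target_species: LAF
# provenance: arm-level rearrangement table for TML chromosomes 4, 6, 8 and 9 in the African elephant (published comparative painting data)
probe	targets
4p	23
4q-prox	12p-qprox
4q-dist	7
6p	1p
6q	8
8p	17q-dist
8q-prox	21pq-prox
8q-dist	22
9p	14q-dist
9q	19
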