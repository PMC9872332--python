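# probe_species: TML
# target_species: PCA
# provenance: arm-level rearrangement table for TML chromosomes 4, 6, 8 and 9 in the hyrax (published comparative painting data)
probe	targets
4p	24
4q	7
6p	16q-dist
6q	9
8p	10pq-prox
8q	18
9p	20
9q	14
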