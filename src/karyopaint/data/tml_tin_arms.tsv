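# probe_species: TML
# target_species: TIN
# provenance: arm-level rearrangement table for TML chromosomes 4, 6, 8 and 9 in the Amazonian manatee
probe	targets
4p	26
4q	16
6p	27
6q	15
8p	22
8q	19
9p	25
9q	24
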