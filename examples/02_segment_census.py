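"""Census of homologous segments in the TML→TIN painting map.

Counts how many homologous segments the whole-chromosome probe set
reveals in the target karyotype and which probes split over two target
chromosomes.
"""

from karyopaint import count_homologous_segments, load_fixture

m = load_fixture("tml_tin")
census = count_homologous_segments(m)

print(f"{m.probe_species} probes on {m.target_species}: {census.total} homologous segments")
print(f"probes with two hybridisation signals: {', '.join(census.multi_signal_probes)}")
for probe in census.multi_signal_probes:
    targets = ", ".join(m.target_chromosomes_of(probe))
    print(f"  TML {probe} -> TIN {targets}")

print()
print("Each split probe marks one fission (or, read ancestrally, one fusion):")
print("four split probes account for the whole 2n = 48 vs 56 difference.")
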