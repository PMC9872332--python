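"""Human-chromosome syntenic associations in the Amazonian manatee.

Human (HSA) painting data exist for the Florida manatee (TML) but not
for the Amazonian manatee (TIN); composing HSA→TML homologies with the
TML→TIN painting map infers which classic cladistic markers (HSA 5/21
for Afrotheria, 2/3, 8/22, 18/19 for Paenungulata, ...) TIN retains.
"""

from karyopaint import (
    compose_maps,
    detect_syntenic_associations,
    load_fixture,
    painting_map_between,
)

matrix = load_fixture("apk_matrix")
hsa_tml = painting_map_between(matrix, "HSA", "TML")
composed = compose_maps(hsa_tml, load_fixture("tml_tin"))

published = load_fixture("hsa_assoc_published")
report = detect_syntenic_associations(composed, [sorted(a.pair) for a in published])

for assoc in published:
    hits = report.hits_for(assoc.pair)
    where = ", ".join(f"TIN {h.target_chromosome}" for h in hits) or "absent"
    print(f"HSA {assoc.label:>5} ({assoc.clade:10s}): {where}")

print()
print("Presence of 5/21 marks TIN as Afrotherian; 2/3, 18/19 and 8/22 as a")
print("paenungulate; the lost 4/8 matches every other Paenungulata karyotype.")
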