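"""Rearrangement events per lineage from the ancestral Paenungulata karyotype.

Counts fusions, fissions and annotated inversions/repositionings along
each lineage of the ancestral homology matrix, then converts totals to
chromosomal change rates per million years.
"""

from karyopaint import compute_change_rate, count_lineage_events, load_fixture
from karyopaint.report import PAENUNGULATA_DIVERGENCE_MYR, TRICHECHUS_DIVERGENCE_MYR

matrix = load_fixture("apk_matrix")

print(f"events on each lineage from the ancestral karyotype (2n = {matrix.caption_2n}):")
totals = {}
for taxon in ("TIN", "TML", "LAF", "PCA"):
    lin = count_lineage_events(matrix, taxon)
    totals[taxon] = lin.summary.total
    rate = compute_change_rate(lin.summary.total, PAENUNGULATA_DIVERGENCE_MYR)
    counts = ", ".join(f"{k.replace('_', ' ')}={v}" for k, v in sorted(lin.summary.counts.items()))
    print(f"  APK→{taxon}: {counts}; total {lin.summary.total} ({rate:.2f} changes/myr)")
    for note in lin.unresolved:
        print(f"      unresolved: {note}")

pair_rate = compute_change_rate(5, TRICHECHUS_DIVERGENCE_MYR)
print()
print(f"TML vs TIN: 4 Robertsonian events + 1 pericentric inversion over "
      f"{TRICHECHUS_DIVERGENCE_MYR} myr = {pair_rate:.2f} changes/myr")
print(f"lineage totals order {' < '.join(sorted(totals, key=totals.get))}: the Amazonian")
print("manatee keeps the most ancestral-like karyotype, the Florida manatee the most derived.")
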