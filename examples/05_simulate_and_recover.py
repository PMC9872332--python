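"""Simulate karyotype evolution, then recover the events from painting alone.

A known history of centric fusions and fissions is applied to a
synthetic ancestral karyotype; the emitted painting map is handed to the
event-inference machinery and scored against the truth log.
"""

from karyopaint import evaluate_recovery, infer_pairwise_events, simulate_lineage
from karyopaint.simulate import SimConfig

cfg = SimConfig(
    ancestral_pairs=27,
    acrocentric_fraction=0.6,
    fusions=4,
    fissions=1,
    inversions=1,
    seed=42,
)
result = simulate_lineage(cfg)
anc, der = result.log.ancestral, result.derived

print(f"ancestral: 2n = {anc.diploid_number}, FN = {anc.fundamental_number}")
print(f"derived:   2n = {der.diploid_number}, FN = {der.fundamental_number}")
print("(Robertsonian events move 2n by 2 apiece and leave FN untouched)")

inferred = infer_pairwise_events(result.map, anc, der)
report = evaluate_recovery(result.log, inferred.events)
print()
for etype, (truth, found) in report.per_type.items():
    print(f"{etype}: simulated {truth}, inferred {found}")
print(f"identifiability: {report.identifiability}; exact match: {report.exact_match}")
print()
print("Painting cannot see the simulated inversion (annotation-only event),")
print("but every fusion/fission leaves a two-signal fingerprint in the map.")
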