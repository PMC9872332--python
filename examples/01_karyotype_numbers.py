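"""Diploid and fundamental numbers of the two manatee karyotypes.

The Amazonian manatee (TIN) and the Florida manatee (TML) differ by 8 in
diploid number yet carry the same autosomal arm count — the signature of
Robertsonian (centric) fusion/fission divergence.
"""

from karyopaint import compute_diploid_number, compute_fundamental_number, load_fixture

for code in ("TIN", "TML", "APK"):
    k = load_fixture(f"karyotype_{code}")
    try:
        fn = compute_fundamental_number(k)
    except Exception:
        fn = None  # morphology unreported for the ancestral complement
    fn_text = fn if fn is not None else "not derivable (morphology unreported)"
    print(f"{code}: 2n = {compute_diploid_number(k)}, autosomal FN = {fn_text}")

print()
print("Equal FN at unequal 2n means the missing pairs were centric fusions:")
print("arm counts are conserved while chromosome counts change by 2 per event.")
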