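"""Tokenize cysteine spacing and assign framework identifiers.

The grammar classifies consecutive cysteines as CC (adjacent), CXC (one
residue apart) or C-C (further apart); the catalog maps token patterns to
the numbered framework classes of spider ICK surveys.
"""

import ickkit as ik

catalog = ik.load_default_catalog()
print("packaged catalog:")
for ident in catalog.identifiers:
    fw = catalog.get(ident)
    numeral = catalog.numeral(ident) or "-"
    print(f"  {ident:>5} (numeral {numeral:>4}): {fw.motif}")

mature = "ASCLEGCSKHCCGYNCACQMGCKCDF"  # an 8-cysteine mature peptide
fw = ik.tokenize_cysteines(mature)
print(f"\npeptide {mature}")
print(f"tokens  {fw.tokens}")
print(f"motif   {fw.motif}")
print(f"class   {ik.assign_framework(mature, catalog)!r}")

# The retention rule keeps the framework classes covering the top 80% of
# peptides in the largest family (counts here mirror a typical survey).
counts = {"8.0": 538, "6.0": 123, "10.0": 117, "12.0": 100}
print("\ntop-80% coverage retains:", ik.top_coverage_filter(counts, 0.8))
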