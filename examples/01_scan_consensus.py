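"""Scan the 64-aa tandem-CWCH2 consensus and report the motif's features.

The consensus carries two CWCH2 zinc fingers (each Cys-X-Trp-...-Cys-...-
His-...-His) joined by an 8-residue linker; this is the package's worked
example, with every coordinate known by hand.
"""

from tcwch2 import TCWCH2_CONSENSUS, ProteinRecord, SpacingConfig, annotate_tandems

record = ProteinRecord(id="consensus", sequence=TCWCH2_CONSENSUS)
(tandem,) = annotate_tandems(record, SpacingConfig.strict())

print(f"sequence ({len(record.sequence)} aa): {record.sequence}")
print("ZF1 anchors (C,C,H,H, 1-based):", tuple(a + 1 for a in tandem.zf1.anchors))
print("ZF2 anchors (C,C,H,H, 1-based):", tuple(a + 1 for a in tandem.zf2.anchors))
print(f"linker: {tandem.linker_seq!r} ({tandem.linker_len} aa)")
print(f"phi1/phi2 (residue after each finger's first His): {tandem.phi1}/{tandem.phi2}")
print(f"extra sequence beyond the 4-residue intra-Cys baseline: {tandem.extra1}/{tandem.extra2}")
print(f"canonical TGE(K/R)P linker present: {tandem.has_tgekp}")
print()
print("Both fingers carry the tryptophan two residues after their first")
print("cysteine (positions 5 and 38), so the pair forms one tandem motif;")
print("the hydrophobic phi residues (V, I) face the tryptophans in the core.")
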