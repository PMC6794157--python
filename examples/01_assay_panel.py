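"""Inspect the packaged 10-reaction assay panel and self-validate it.

Each multiplex reaction amplifies two KIR targets and the STAT6 reference,
read on three fluorescence channels.  The validator recomputes every
printed primer/probe length, GC% and amplicon size from the sequences.
"""

from qkat import load_assay_panel, validate_panel

panel = load_assay_panel()
print(f"{len(panel.reactions)} multiplex reactions")
for rxn in panel.reactions:
    a, b = rxn.targets
    print(f"  reaction {rxn.reaction_number:>2}: {a:<10} + {b:<10} "
          f"(+ {rxn.reference_locus}); channels "
          f"{rxn.channel_map[a]} / {rxn.channel_map[b]}")

discrepancies = validate_panel(panel)
print(f"\nself-validation: {len(discrepancies)} discrepancies")
# 0 discrepancies means every printed table value is reproduced by
# computation: the fixture carries no transcription errors.

amp = panel.printed_amplicon
print(f"example amplicons: 3DL2ex4 {amp['3DL2ex4']} bp, 2DS4Del {amp['2DS4Del']} bp")
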