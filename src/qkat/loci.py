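"""Locus and channel constants for the 10-reaction KIR typing panel.

The panel types 20 measurements: 16 KIR genes/variant groups, with 3DL1 and
3DL2 each measured twice (exon-4 and exon-9 assays) and 2DS4 resolved into
total, full-length and 22-bp-deletion forms.  STAT6 is the two-copy genomic
reference amplified in every reaction.
"""

LOCI: tuple[str, ...] = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DP1", "2DL1", "3DP1", "2DL4",
    "3DL1ex4", "3DL1ex9", "3DS1", "2DL5", "2DS3", "2DS5", "2DS1",
    "2DS4Total", "2DS4FL", "2DS4Del", "3DL2ex4", "3DL2ex9",
)

#: Framework measurements expected at two copies in essentially all samples.
FRAMEWORK_LOCI: tuple[str, ...] = ("3DL3", "3DP1", "2DL4", "3DL2ex4", "3DL2ex9")

REFERENCE_LOCUS = "STAT6"

#: Fluorescence filter names (excitation-emission bands, nm) and their roles.
CHANNEL_FAM = "465-510"      # FAM-labelled probe: first KIR target
CHANNEL_YELLOW = "533-580"   # ATTO550 (VIC/HEX/Yellow555 slot): STAT6
CHANNEL_RED = "618-660"      # ATTO647N (Cy5 slot): second KIR target
CHANNELS: tuple[str, ...] = (CHANNEL_FAM, CHANNEL_YELLOW, CHANNEL_RED)

#: Accepted aliases for the three filters as they appear in instrument exports.
CHANNEL_ALIASES: dict[str, str] = {
    CHANNEL_FAM: CHANNEL_FAM,
    CHANNEL_YELLOW: CHANNEL_YELLOW,
    CHANNEL_RED: CHANNEL_RED,
    "FAM (465-510)": CHANNEL_FAM,
    "VIC/HEX/Yellow555 (533-580)": CHANNEL_YELLOW,
    "Cy5/Cy5.5 (618-660)": CHANNEL_RED,
    "green": CHANNEL_FAM,
    "yellow": CHANNEL_YELLOW,
    "red": CHANNEL_RED,
}
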