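"""Published worked values used by the composition tests.

Per-base percentages (T, C, A, G, to one decimal) and the 3-decimal AT/GC
skews of the two green-belly bug mitogenomes, per partition, as printed in
the source composition table.  Skews are ratio statistics, so they are
recomputable from the percentages alone.
"""

# species -> partition -> (T%, C%, A%, G%, AT skew, GC skew)
PRINTED_COMPOSITION = {
    "D_melacanthus": {
        "Full genome": (31.5, 15.0, 42.5, 11.0, 0.149, -0.154),
        "PCGs":        (38.8, 14.9, 32.5, 13.8, -0.088, -0.038),
        "tRNAs":       (38.0, 10.6, 37.7, 13.7, -0.004, 0.128),
        "rRNAs":       (43.1, 9.5, 31.1, 16.3, -0.162, 0.264),
        "rrnL":        (42.3, 11.0, 29.2, 17.5, -0.183, 0.228),
        "rrnS":        (43.7, 8.3, 32.3, 15.3, -0.150, 0.297),
    },
    "D_furcatus": {
        "Full genome": (29.9, 16.4, 42.5, 11.2, 0.174, -0.188),
        "PCGs":        (38.1, 15.4, 32.4, 14.1, -0.081, -0.044),
        "tRNAs":       (37.8, 10.6, 38.0, 13.6, 0.003, 0.124),
        "rRNAs":       (42.9, 9.7, 30.9, 16.5, -0.163, 0.260),
        "rrnL":        (42.0, 11.3, 29.2, 17.5, -0.180, 0.215),
        "rrnS":        (43.6, 8.5, 32.3, 15.7, -0.149, 0.298),
    },
}

# mtSSR table: species -> list of (motif, n_units, size, start, end, location)
PRINTED_SSRS = {
    "D_melacanthus": [
        ("AAAT", 3, 12, 8419, 8430, "nad4"),
        ("TAT", 6, 18, 10168, 10185, "nad6"),
        ("AATT", 3, 12, 13899, 13910, "Intergenic region"),
    ],
    "D_furcatus": [
        ("AAAC", 3, 12, 6689, 6700, "nad5"),
        ("AAAT", 3, 12, 8291, 8302, "nad4"),
        ("AATT", 3, 12, 13770, 13781, "Intergenic region"),
    ],
}
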