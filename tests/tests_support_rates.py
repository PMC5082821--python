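"""Published per-clone yearly mutation rates (UV, endogenous, total) for
the two donors' hip and forearm clones, used as input to the donor-level
aggregation checks."""

TABLE1_ROWS = [
    # sample, donor, site, uv_rate, endogenous_rate, total_rate
    ("D1-R-H1", "D1", "hip", 5, 13, 22),
    ("D1-R-H2", "D1", "hip", 2, 9, 11),
    ("D1-L-H", "D1", "hip", 2, 7, 9),
    ("D1-R-F", "D1", "forearm", 3, 12, 17),
    ("D1-L-F1", "D1", "forearm", 17, 51, 86),
    ("D1-L-F2", "D1", "forearm", 11, 36, 63),
    ("D2-R-H", "D2", "hip", 9, 24, 34),
    ("D2-L-H", "D2", "hip", 20, 41, 80),
    ("D2-R-F", "D2", "forearm", 54, 127, 220),
    ("D2-L-F", "D2", "forearm", 38, 84, 148),
]
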