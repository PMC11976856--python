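"""Published per-endpoint potency magnitudes and consensus values.

Each row: particle -> ((LDH, ATP, CTB, beta_avg) for A549,
                       (LDH, ATP, CTB, beta_avg) for J774A.1).
SILICA rows print 3 decimals, TITANIA rows 4 decimals.  The RANKS_* vectors
pair each cell line's printed beta_avg sequence with its printed dense ranks.
"""

SILICA = {
    "SiNP-12":      ((0.065, 0.037, 0.010, 0.037), (0.355, 0.360, 0.263, 0.326)),
    "SiNP-15P":     ((0.040, 0.033, 0.015, 0.029), (0.068, 0.027, 0.006, 0.034)),
    "SiNP-15 C3":   ((0.010, 0.018, 0.018, 0.015), (0.001, 0.012, 0.005, 0.006)),
    "SiNP-15 C11":  ((0.053, 0.008, 0.008, 0.023), (0.011, 0.024, 0.009, 0.015)),
    "SiNP-15 NH2":  ((0.071, 0.012, 0.013, 0.032), (0.016, 0.011, 0.016, 0.014)),
    "SiNP-15 PEG":  ((0.002, 0.021, 0.010, 0.011), (0.001, 0.026, 0.001, 0.009)),
    "SiNP-30 P":    ((0.018, 0.018, 0.018, 0.018), (0.050, 0.012, 0.001, 0.021)),
    "SiNP-30 C3":   ((0.019, 0.009, 0.022, 0.017), (0.005, 0.004, 0.007, 0.005)),
    "SiNP-30 C11":  ((0.142, 0.016, 0.019, 0.059), (0.027, 0.015, 0.003, 0.015)),
    "SiNP-30 NH2":  ((0.083, 0.051, 0.046, 0.060), (0.060, 0.008, 0.012, 0.027)),
    "SiNP-30 PEG":  ((0.001, 0.014, 0.011, 0.009), (0.004, 0.0001, 0.007, 0.004)),
    "SiNP-50 P":    ((0.021, 0.010, 0.013, 0.015), (0.055, 0.002, 0.002, 0.019)),
    "SiNP-50 C3":   ((0.057, 0.016, 0.005, 0.026), (0.021, 0.019, 0.010, 0.016)),
    "SiNP-50 C11":  ((0.108, 0.010, 0.006, 0.041), (0.029, 0.004, 0.003, 0.012)),
    "SiNP-50 NH2":  ((0.021, 0.024, 0.004, 0.016), (0.027, 0.001, 0.008, 0.012)),
    "SiNP-50 PEG":  ((0.007, 0.004, 0.004, 0.005), (0.000, 0.018, 0.011, 0.010)),
    "SiNP-75 P":    ((0.019, 0.009, 0.002, 0.010), (0.114, 0.021, 0.022, 0.052)),
    "SiNP-75 C3":   ((0.009, 0.001, 0.006, 0.005), (0.010, 0.006, 0.012, 0.009)),
    "SiNP-75 C11":  ((0.020, 0.007, 0.001, 0.010), (0.016, 0.007, 0.018, 0.014)),
    "SiNP-75 NH2":  ((0.032, 0.006, 0.005, 0.014), (0.096, 0.020, 0.027, 0.047)),
    "SiNP-75 PEG":  ((0.006, 0.006, 0.005, 0.006), (0.002, 0.002, 0.019, 0.008)),
    "SiNP-100 P":   ((0.032, 0.015, 0.001, 0.016), (0.138, 0.019, 0.029, 0.062)),
    "SiNP-100 C3":  ((0.007, 0.006, 0.009, 0.007), (0.003, 0.009, 0.013, 0.008)),
    "SiNP-100 C11": ((0.014, 0.001, 0.008, 0.008), (0.011, 0.005, 0.005, 0.007)),
    "SiNP-100 NH2": ((0.016, 0.005, 0.030, 0.017), (0.026, 0.001, 0.013, 0.013)),
    "SiNP-100 PEG": ((0.0004, 0.048, 0.007, 0.018), (0.013, 0.015, 0.001, 0.010)),
}

TITANIA = {
    "Ti-01": ((0.0413, 0.0172, 0.0348, 0.0311), (0.0319, 0.0095, 0.0117, 0.0177)),
    "Ti-02": ((0.0194, 0.0075, 0.0298, 0.0189), (0.0051, 0.0052, 0.0156, 0.0086)),
    "Ti-03": ((0.0212, 0.0206, 0.0327, 0.0248), (0.0143, 0.0131, 0.0157, 0.0144)),
    "Ti-04": ((0.0294, 0.0094, 0.0337, 0.0242), (0.0422, 0.0200, 0.0107, 0.0243)),
    "Ti-05": ((0.0342, 0.0051, 0.0318, 0.0237), (0.0074, 0.0205, 0.0104, 0.0128)),
    "Ti-06": ((0.0379, 0.0045, 0.0228, 0.0217), (0.0210, 0.0163, 0.0066, 0.0147)),
    "Ti-07": ((0.0331, 0.0017, 0.0260, 0.0203), (0.0190, 0.0133, 0.0135, 0.0153)),
    "Ti-08": ((0.0348, 0.0057, 0.0250, 0.0218), (0.0424, 0.0192, 0.0337, 0.0318)),
    "Ti-09": ((0.0349, 0.0141, 0.0114, 0.0201), (0.0041, 0.0177, 0.0166, 0.0128)),
    "Ti-10": ((0.0396, 0.0269, 0.0295, 0.0320), (0.0022, 0.0140, 0.0183, 0.0115)),
    "Ti-11": ((0.0569, 0.0348, 0.0235, 0.0384), (0.0546, 0.0196, 0.0101, 0.0281)),
    "TiO2":  ((0.0380, 0.0268, 0.0285, 0.0311), (0.0079, 0.0218, 0.0033, 0.0110)),
}

# (particles, beta_avg vector, printed dense ranks)
RANKS_SILICA_A549 = (
    ("SiNP-12", "SiNP-15P", "SiNP-15 C3", "SiNP-15 C11",
     "SiNP-15 NH2", "SiNP-15 PEG", "SiNP-30 P", "SiNP-75 P"),
    (0.037, 0.029, 0.015, 0.023, 0.032, 0.011, 0.018, 0.010),
    (1, 3, 6, 4, 2, 7, 5, 8),
)
RANKS_SILICA_J774 = (
    RANKS_SILICA_A549[0],
    (0.326, 0.034, 0.006, 0.015, 0.014, 0.009, 0.021, 0.052),
    (1, 3, 8, 5, 6, 7, 4, 2),
)
_TI_PARTICLES = ("Ti-01", "Ti-02", "Ti-03", "Ti-04", "Ti-05", "Ti-06",
                 "Ti-07", "Ti-08", "Ti-09", "Ti-10", "Ti-11", "TiO2")
RANKS_TITANIA_A549 = (
    _TI_PARTICLES,
    (0.031, 0.019, 0.025, 0.024, 0.024, 0.022, 0.020, 0.022, 0.020, 0.032,
     0.038, 0.031),
    (3, 8, 4, 5, 5, 6, 7, 6, 7, 2, 1, 3),
)
RANKS_TITANIA_J774 = (
    _TI_PARTICLES,
    (0.018, 0.009, 0.014, 0.024, 0.013, 0.015, 0.015, 0.032, 0.013, 0.012,
     0.028, 0.011),
    (4, 10, 6, 3, 7, 5, 5, 1, 7, 8, 2, 9),
)
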