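"""Builtin gene panels.

``table1`` is the published 25-gene ovarian-cancer panel, transcribed
row-by-row (gene symbol, screening P value, direction). Direction "high"
means above-median expression was associated with better overall survival
(high_good); "low" means above-median expression was associated with worse
survival (low_good). The first P value is stored verbatim as 0 (rounded in
the source).
"""

# (gene, screen_p, direction token)
TABLE1 = (
    ("AKT2", 0.0, "low"),
    ("FOSB", 0.005, "low"),
    ("CITED4", 0.009, "high"),
    ("CYBA", 0.012, "high"),
    ("JUNB", 0.013, "low"),
    ("CYP27B1", 0.014, "high"),
    ("FOS", 0.014, "low"),
    ("NFIX", 0.027, "low"),
    ("TXNRD1", 0.041, "low"),
    ("USP14", 0.054, "high"),
    ("RIT1", 0.058, "low"),
    ("KEAP1", 0.0581, "high"),
    ("CYP3A7", 0.061, "high"),
    ("TXN", 0.07, "low"),
    ("GCLC", 0.07, "high"),
    ("AKR7A3", 0.072, "low"),
    ("JUN", 0.074, "low"),
    ("CUL3", 0.076, "low"),
    ("GSTA3", 0.076, "high"),
    ("PMF1", 0.078, "high"),
    ("PPARG", 0.106, "low"),
    ("SOD1", 0.122, "high"),
    ("ABCC4", 0.123, "high"),
    ("GSTM3", 0.14, "low"),
    ("NOX4", 0.142, "high"),
)

BUILTIN_PANELS = {"table1": TABLE1}
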