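"""Hand-computed reference values for the molecular indices.

Each row: formula, DBE, DBE_AI, AI_mod, NOSC, compound category, oxygen
class — worked out by hand from the definitions (DBE = 1 + C - H/2 +
(N+P)/2; DBE_AI = 1 + C - O/2 - S - (N+P+H)/2; AI_mod = DBE_AI /
(C - O/2 - N - S - P) clamped at 0; NOSC = 4 - (4C + H - 3N - 2O + 5P -
2S)/C), independent of the implementation.
"""

INDEX_ORACLE = [
    # formula, dbe, dbe_ai, ai_mod, nosc, category, oxygen_class
    ("C6H6", 4, 4, 4 / 6, -1.0, "aromatic", "O_poor"),
    ("C6H12O6", 1, -2, 0.0, 0.0, "unsaturated", "O_rich"),
    ("C1H4", 0, 0, 0.0, -4.0, "saturated", "O_poor"),
    ("C16H34", 0, 0, 0.0, -2.125, "saturated", "O_poor"),
    ("C14H6O2", 12, 11, 11 / 13, -1 / 7, "aromatic", "O_poor"),
    ("C2H4O2", 1, 0, 0.0, 0.0, "unsaturated", "O_rich"),
    ("C10H10O2N1S1", 6.5, 3.5, 0.5, -0.1, "highly_unsaturated", "O_poor"),
    ("C8H8O4", 5, 3, 0.5, 0.0, "highly_unsaturated", "O_rich"),
    ("C5H5N5", 6, 1, 0.0, 2.0, "highly_unsaturated", "O_poor"),
    ("C6H14O4", 0, -2, 0.0, -1.0, "saturated", "O_rich"),
    ("C3H9O6P1", 0, -4, 0.0, -2 / 3, "saturated", "O_rich"),
    ("C27H46O1", 5, 4.5, 4.5 / 26.5, 4 - 152 / 27, "unsaturated", "O_poor"),
    ("C15H16O8", 8, 4, 4 / 11, 0.0, "highly_unsaturated", "O_rich"),
    ("C13H18O7", 5, 1.5, 1.5 / 9.5, -4 / 13, "highly_unsaturated", "O_rich"),
    ("C20H12", 15, 15, 0.75, -0.6, "aromatic", "O_poor"),
    ("C2H6S1", 0, -1, 0.0, -2.0, "saturated", "O_poor"),
    ("C9H11N1O3", 5, 2.5, 2.5 / 6.5, -2 / 9, "highly_unsaturated", "O_poor"),
    ("C12H8S1", 9, 8, 8 / 11, -0.5, "aromatic", "O_poor"),
    ("C1H2O2", 1, 0, 0.0, 2.0, "unsaturated", "O_rich"),
    ("C2H2O4", 2, 0, 0.0, 3.0, "highly_unsaturated", "O_rich"),
    ("C10H14N2", 5, 3, 0.375, -0.8, "highly_unsaturated", "O_poor"),
    ("C18H34O2", 2, 1, 1 / 17, -5 / 3, "unsaturated", "O_poor"),
]
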