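"""Per-formula molecular indices and compound categories; per-sample I_Deg.

DBE counts rings+double bonds; DBE_AI and AI_mod quantify aromaticity; NOSC
the carbon oxidation state. The degradation index I_Deg compares intensity
in ten reference formulas that track degraded vs fresh organic matter.
"""

from domdiv import MolecularFormula, i_deg, index_table, load_ideg_sets

table = index_table(["C6H6", "C6H12O6", "C14H6O2", "C16H34", "C10H10O2N1S1"])
print(table[["dbe", "dbe_ai", "ai_mod", "nosc", "category", "oxygen_class"]])

neg, pos = load_ideg_sets()
fresh_dom = {str(f): 1.0 for f in pos} | {str(neg[0]): 0.2}
degraded_dom = {str(f): 1.0 for f in neg} | {str(pos[0]): 0.2}
print(f"\nI_Deg of a fresh-like sample:    {i_deg(fresh_dom):.3f}")
print(f"I_Deg of a degraded-like sample: {i_deg(degraded_dom):.3f}")

# Aromatic formulas (AI_mod > 0.5) and saturated ones (DBE = 0) bracket the
# compound-category spectrum; I_Deg rises from ~0 (fresh) toward 1 as the
# degradation-associated reference formulas dominate.
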