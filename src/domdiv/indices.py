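"""Per-formula molecular indices, compound categories, and the degradation index.

The indices are the standard FT-ICR MS descriptors of DOM composition:

* DBE, double bond equivalents: rings plus double bonds of the neutral
  molecule, ``1 + C - H/2 + (N + P)/2``.
* DBE_AI: the DBE of the carbon skeleton after discounting heteroatoms that
  can carry unsaturation, ``1 + C - O/2 - S - (N + P + H)/2``. Because every
  term is a half-integer multiple, DBE_AI falls on a 0.5 grid, which makes
  it a natural histogram variable.
* AI_mod, modified aromaticity index: DBE_AI divided by the number of
  carbons available for C=C bonding, ``C - O/2 - N - S - P``, clamped to 0
  when numerator or denominator is non-positive. Values above 0.5 indicate
  aromatic structures; values above 1 are possible for condensed cores.
* NOSC, nominal oxidation state of carbon:
  ``4 - (4C + H - 3N - 2O + 5P - 2S)/C``; oxidation of a compound becomes
  thermodynamically more favorable as NOSC increases.
* I_Deg, degradation index: the intensity-weighted share of five
  degradation-associated reference formulas relative to ten reference
  formulas in total, an indicator of microbial/diagenetic alteration.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import AssignedSample, MolecularFormula

__all__ = [
    "dbe",
    "dbe_ai",
    "ai_mod",
    "nosc",
    "classify",
    "index_table",
    "i_deg",
    "load_ideg_sets",
    "CATEGORIES",
]

CATEGORIES = ("aromatic", "highly_unsaturated", "unsaturated", "saturated")


def dbe(f: MolecularFormula) -> float:
    """Double bond equivalents: 1 + C - H/2 + (N + P)/2."""
    return 1.0 + f.C - f.H / 2.0 + (f.N + f.P) / 2.0


def dbe_ai(f: MolecularFormula) -> float:
    """DBE of the molecular core (numerator of AI_mod); may be negative."""
    return 1.0 + f.C - f.O / 2.0 - f.S - (f.N + f.P + f.H) / 2.0


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index, clamped to 0 for non-positive terms."""
    num = dbe_ai(f)
    den = f.C - f.O / 2.0 - f.N - f.S - f.P
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


def nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon of the neutral molecule."""
    return 4.0 - (4.0 * f.C + f.H - 3.0 * f.N - 2.0 * f.O + 5.0 * f.P - 2.0 * f.S) / f.C


def classify(f: MolecularFormula) -> tuple[str, str]:
    """Compound category and oxygen class of a formula.

    Categories: saturated (DBE = 0), else aromatic (AI_mod > 0.5), else
    unsaturated (H/C >= 1.5) or highly unsaturated (H/C < 1.5) — evaluated
    in that order so the four classes partition formula space. The oxygen
    class splits at O/C = 0.5 (``O_rich`` when O/C >= 0.5).
    """
    oxygen = "O_rich" if f.O / f.C >= 0.5 else "O_poor"
    if dbe(f) == 0:
        return "saturated", oxygen
    if ai_mod(f) > 0.5:
        return "aromatic", oxygen
    if f.H / f.C >= 1.5:
        return "unsaturated", oxygen
    return "highly_unsaturated", oxygen


def index_table(formulas: Iterable[MolecularFormula | str]) -> pd.DataFrame:
    """All per-formula indices as one table, indexed by canonical formula."""
    rows = {}
    for f in formulas:
        if isinstance(f, str):
            f = MolecularFormula.parse(f)
        cat, oxy = classify(f)
        rows[str(f)] = {
            "C": f.C,
            "H": f.H,
            "N": f.N,
            "O": f.O,
            "S": f.S,
            "P": f.P,
            "mass": f.mass,
            "hc": f.H / f.C,
            "oc": f.O / f.C,
            "nc": f.N / f.C,
            "dbe": dbe(f),
            "dbe_ai": dbe_ai(f),
            "ai_mod": ai_mod(f),
            "nosc": nosc(f),
            "category": cat,
            "oxygen_class": oxy,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "formula"
    return table


def load_ideg_sets() -> tuple[list[MolecularFormula], list[MolecularFormula]]:
    """Default (negative, positive) I_Deg reference sets.

    The ten CHO formulas of Flerus et al. (2012): five whose relative
    abundance tracks degraded DOM ("negative" set) and five tracking fresh
    DOM ("positive" set). Shipped as package data so alternative sets can be
    supplied in the same CSV layout (columns ``formula``, ``role``).
    """
    ref = importlib.resources.files("domdiv").joinpath("data/ideg_formulas.csv")
    with ref.open() as fh:
        table = pd.read_csv(fh)
    neg = [MolecularFormula.parse(s) for s in table.loc[table["role"] == "neg", "formula"]]
    pos = [MolecularFormula.parse(s) for s in table.loc[table["role"] == "pos", "formula"]]
    return neg, pos


def i_deg(
    sample: AssignedSample | Mapping[str, float] | pd.Series,
    neg_set: Sequence[MolecularFormula] | None = None,
    pos_set: Sequence[MolecularFormula] | None = None,
) -> float:
    """Degradation index of one sample from summed reference-set intensities.

    ``i_deg = sum(neg) / (sum(neg) + sum(pos))``; 0 means fresh, 1 fully
    degradation-dominated. Returns NaN (with a warning) when no reference
    formula was detected. ``sample`` may be an :class:`AssignedSample` or a
    mapping of canonical formula strings to intensities.
    """
    if neg_set is None or pos_set is None:
        default_neg, default_pos = load_ideg_sets()
        neg_set = neg_set if neg_set is not None else default_neg
        pos_set = pos_set if pos_set is not None else default_pos
    neg_keys = {str(f) for f in neg_set}
    pos_keys = {str(f) for f in pos_set}
    if neg_keys & pos_keys:
        raise ValueError("neg_set and pos_set must be disjoint")
    if isinstance(sample, AssignedSample):
        intensities = sample.intensity_by_formula()
    else:
        intensities = pd.Series(dict(sample), dtype=float)
    neg_sum = float(intensities.reindex(sorted(neg_keys)).fillna(0.0).sum())
    pos_sum = float(intensities.reindex(sorted(pos_keys)).fillna(0.0).sum())
    if neg_sum + pos_sum == 0:
        warnings.warn("no I_Deg reference formula detected; index undefined", stacklevel=2)
        return float("nan")
    return neg_sum / (neg_sum + pos_sum)
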