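"""Molecular formulas and exact-mass CHNOSP assignment for negative-mode FT-ICR MS.

Masses are measured as singly charged, even-electron deprotonated ions
([M-H]-); assignment searches all CHNOSP formulas whose neutral monoisotopic
mass matches the neutralized measured mass within a ppm tolerance, then
applies chemical-plausibility filters (integer DBE >= 0, H/C and O/C bounds)
and a deterministic heteroatom-parsimony tie-break.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularFormula",
    "AssignmentConfig",
    "AssignedSample",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "formula_mass",
    "neutral_mass",
    "ion_mz",
    "enumerate_candidates",
    "apply_chemical_filters",
    "assign_sample",
]

#: Monoisotopic atomic masses (Da) of the light isotopes used throughout.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Mass of a proton (Da); [M-H]- neutralization adds this back to m/z.
PROTON_MASS: float = 1.00727646

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "P")

_FORMULA_RE = re.compile(r"([CHONSP])(\d+)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral CHNOSP molecule.

    The canonical text form writes every element with an explicit count in
    the fixed order C, H, O, N, S, P (e.g. ``C10H12O5N1S0P0``), which makes
    it unique and sortable as a plain string column header.
    """

    C: int
    H: int
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a nonnegative integer")
        if self.C < 1:
            raise ValueError("formula must contain at least one carbon")
        if self.H < 1:
            raise ValueError("formula must contain at least one hydrogen")

    @property
    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.C, self.H, self.N, self.O, self.S, self.P)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return formula_mass(self)

    def __str__(self) -> str:
        return f"C{self.C}H{self.H}O{self.O}N{self.N}S{self.S}P{self.P}"

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a canonical or compact formula string such as ``C6H12O6``."""
        counts = {el: 0 for el in ELEMENTS}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(text) or pos == 0:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(**counts)

    def sort_key(self) -> tuple:
        """Deterministic ordering: exact mass, then element counts."""
        return (self.mass, self.counts)


def formula_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass (Da) of a formula."""
    return sum(getattr(f, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS)


def neutral_mass(mz: float, charge: int = -1) -> float:
    """Neutral mass of a singly charged deprotonated ion ([M-H]-)."""
    if charge != -1:
        raise ValueError(f"only singly charged [M-H]- ions are supported, got charge={charge}")
    return mz + PROTON_MASS


def ion_mz(f: MolecularFormula) -> float:
    """Theoretical [M-H]- m/z of a neutral formula."""
    return formula_mass(f) - PROTON_MASS


_DEFAULT_RANGES: Mapping[str, tuple[int, int]] = {
    "C": (1, 60),
    "H": (1, 122),
    "O": (0, 40),
    "N": (0, 4),
    "S": (0, 2),
    "P": (0, 1),
}


@dataclass(frozen=True)
class AssignmentConfig:
    """Search ranges, tolerance and plausibility bounds for formula assignment.

    Defaults follow community practice for solid-phase-extracted DOM in
    negative mode: C1-60 H1-122 O0-40 N0-4 S0-2 P0-1, 0.5 ppm tolerance,
    0.3 <= H/C <= 2.5 and O/C <= 1.
    """

    tol_ppm: float = 0.5
    ranges: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(_DEFAULT_RANGES))
    hc_bounds: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.0
    mass_window: tuple[float, float] = (92.0, 1000.0)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        for el in ("C", "H"):
            if el not in self.ranges:
                raise ValueError(f"ranges must include {el}")
        for el, (lo, hi) in self.ranges.items():
            if el not in ELEMENTS or lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {el}: ({lo}, {hi})")

    def range(self, el: str) -> tuple[int, int]:
        return tuple(self.ranges.get(el, (0, 0)))


def enumerate_candidates(
    mass: float, cfg: AssignmentConfig | None = None
) -> list[tuple[MolecularFormula, float]]:
    """All formulas within ``cfg.ranges`` matching ``mass`` within ``cfg.tol_ppm``.

    Returns ``(formula, error_ppm)`` pairs before chemical filtering, sorted
    by absolute mass error then canonical form. The heteroatom loops are
    explicit and the C x O grid is vectorised; for each grid point the
    hydrogen count is solved from the mass residual, so the search is
    exhaustive over the configured ranges.
    """
    cfg = cfg or AssignmentConfig()
    tol_da = mass * cfg.tol_ppm * 1e-6
    mC, mH, mN, mO, mS, mP = (MONOISOTOPIC_MASS[el] for el in ELEMENTS)
    c_lo, c_hi = cfg.range("C")
    h_lo, h_hi = cfg.range("H")
    o_lo, o_hi = cfg.range("O")
    n_lo, n_hi = cfg.range("N")
    s_lo, s_hi = cfg.range("S")
    p_lo, p_hi = cfg.range("P")

    C = np.arange(c_lo, c_hi + 1)
    O = np.arange(o_lo, o_hi + 1)
    grid_mass = C[:, None] * mC + O[None, :] * mO  # (nC, nO)
    # hydrogen counts adjacent to the rounded solution that could still be in
    # tolerance (more than one only when tol_da approaches the H mass)
    h_span = int(tol_da // mH) + 1

    out: list[tuple[MolecularFormula, float]] = []
    for n in range(n_lo, n_hi + 1):
        for s in range(s_lo, s_hi + 1):
            for p in range(p_lo, p_hi + 1):
                rem = mass - (n * mN + s * mS + p * mP) - grid_mass
                h0 = np.rint(rem / mH).astype(np.int64)
                for dh in range(-h_span, h_span + 1):
                    h = h0 + dh
                    err_da = rem - h * mH
                    ok = (h >= h_lo) & (h <= h_hi) & (np.abs(err_da) <= tol_da)
                    for ci, oi in zip(*np.nonzero(ok)):
                        f = MolecularFormula(
                            C=int(C[ci]), H=int(h[ci, oi]), N=n, O=int(O[oi]), S=s, P=p
                        )
                        out.append((f, -err_da[ci, oi] / mass * 1e6))
    # error_ppm is (formula_mass - mass)/mass * 1e6
    out.sort(key=lambda t: (abs(t[1]), str(t[0])))
    return out


def _dbe_value(f: MolecularFormula) -> float:
    return 1.0 + f.C - f.H / 2.0 + (f.N + f.P) / 2.0


def apply_chemical_filters(
    cands: Iterable[tuple[MolecularFormula, float]], cfg: AssignmentConfig | None = None
) -> list[tuple[MolecularFormula, float]]:
    """Keep candidates with integer DBE >= 0 and elemental ratios in bounds.

    Also enforces O >= 4P (phosphorus occurs as phosphate in natural organic
    matter, so P-bearing candidates without the oxygen to support it are
    spurious near-isobars).
    """
    cfg = cfg or AssignmentConfig()
    hc_lo, hc_hi = cfg.hc_bounds
    kept = []
    for f, err in cands:
        dbe = _dbe_value(f)
        if dbe < 0 or dbe != int(dbe):
            continue
        hc = f.H / f.C
        if hc < hc_lo or hc > hc_hi:
            continue
        if f.O / f.C > cfg.oc_max:
            continue
        if f.P and f.O < 4 * f.P:
            continue
        kept.append((f, err))
    return kept


def _tie_break_key(item: tuple[MolecularFormula, float]) -> tuple:
    # P first (rare in DOM and normally requiring isotope confirmation),
    # then joint N+S parsimony, then mass error, then canonical form
    f, err = item
    return (f.P, f.N + f.S, abs(err), str(f))


@dataclass
class AssignedSample:
    """Per-sample formula assignments: the carrier of relative intensities.

    ``assignments`` has columns ``mz``, ``intensity``, ``formula`` (canonical
    string), ``error_ppm``; ``unassigned`` has ``mz``, ``intensity``.
    """

    sample_id: str
    assignments: pd.DataFrame
    unassigned: pd.DataFrame

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        assigned: Sequence[tuple[float, float, MolecularFormula, float]],
        unassigned: Sequence[tuple[float, float]] = (),
    ) -> "AssignedSample":
        a = pd.DataFrame(
            [(mz, it, str(f), err) for mz, it, f, err in assigned],
            columns=["mz", "intensity", "formula", "error_ppm"],
        )
        u = pd.DataFrame(list(unassigned), columns=["mz", "intensity"])
        return cls(sample_id=sample_id, assignments=a, unassigned=u)

    @property
    def formulas(self) -> list[MolecularFormula]:
        """Distinct assigned formulas (peaks mapping to one formula counted once)."""
        return [MolecularFormula.parse(s) for s in self.intensity_by_formula().index]

    def intensity_by_formula(self) -> pd.Series:
        """Summed intensity per canonical formula string."""
        if self.assignments.empty:
            return pd.Series(dtype=float)
        return self.assignments.groupby("formula", sort=True)["intensity"].sum()

    def n_assigned(self) -> int:
        return len(self.assignments)

    def write_csv(self, path) -> None:
        self.assignments.to_csv(path, index=False)


def assign_sample(peaks, cfg: AssignmentConfig | None = None) -> AssignedSample:
    """Assign at most one formula per peak of a calibrated [M-H]- peak list.

    Candidates within tolerance are chemically filtered; surviving ties are
    resolved by (1) fewest N+S+P heteroatoms, (2) smallest absolute ppm
    error, (3) canonical form — fully deterministic given the configuration.
    """
    cfg = cfg or AssignmentConfig()
    lo, hi = cfg.mass_window
    assigned: list[tuple[float, float, MolecularFormula, float]] = []
    unassigned: list[tuple[float, float]] = []
    for mz, intensity in zip(peaks.mz, peaks.intensity):
        m = neutral_mass(float(mz))
        if not (lo <= mz <= hi):
            unassigned.append((float(mz), float(intensity)))
            continue
        cands = apply_chemical_filters(enumerate_candidates(m, cfg), cfg)
        if not cands:
            unassigned.append((float(mz), float(intensity)))
            continue
        f, err = min(cands, key=_tie_break_key)
        assigned.append((float(mz), float(intensity), f, float(err)))
    return AssignedSample.from_records(peaks.sample_id, assigned, unassigned)
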