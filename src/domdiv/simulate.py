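"""Synthetic Antarctic-style lake surveys with known molecular ground truth.

The generator is phenomenological: it does not model reaction kinetics but
reproduces, as inclusion-probability modifiers, the three mechanisms that
shape lake DOM along the salinity (EC) gradient —

* photodegradative loss of aromatics: the probability that a formula is
  present in a lake decays exponentially with the lake's salinity score
  times the formula's aromaticity (AI_mod), with an extra pH penalty for
  oxygen-rich aromatics;
* sulfurization in hypersaline lakes: a fraction of retained formulas is
  converted to an S-bearing analog (one O swapped for one S, preserving the
  validity of the H and DBE grids);
* N-enrichment in proglacial meltwater lakes: N-bearing "fresh" formulas
  are up-weighted.

Lakes draw from a shared formula pool of three source classes (fresh
high-H/C N-bearing, humic-like aromatic, highly unsaturated backbone) plus
small per-lake-type accessory subpools, and each lake type carries a few
planted marker formulas present in every lake of that type and absent
elsewhere — the exact ground truth against which clustering and
indicator-formula recovery are scored. Lake coordinates are drawn
independently of all environmental variables, so composition tracks the
environment but not space.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .formulas import MolecularFormula, AssignmentConfig, apply_chemical_filters, ion_mz
from .indices import ai_mod, classify, dbe
from .peaklists import LAKE_TYPES, PeakList, write_peaklist

__all__ = [
    "SurveyConfig",
    "SurveyResult",
    "generate_formula_pool",
    "generate_lake",
    "generate_survey",
    "write_survey",
]


@dataclass(frozen=True)
class SurveyConfig:
    """Parameters of a synthetic lake survey; ``seed`` is mandatory."""

    n_lakes: int = 40
    lake_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.25 for t in LAKE_TYPES}
    )
    pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"fresh": 700, "aromatic": 600, "highly_unsaturated": 900}
    )
    degradation_strength: float = 0.45
    ph_penalty: float = 0.4
    sulfurization_fraction: float = 0.3
    n_enrichment_fraction: float = 0.5
    base_rate: float = 0.85
    accessory_size: int = 100
    accessory_rate_in: float = 0.95
    accessory_rate_out: float = 0.04
    n_exclusive_per_type: int = 15
    intensity_mu: float = 16.0  # ln-scale mean of lognormal intensities (a.u.)
    intensity_sigma: float = 1.0
    mass_error_ppm: float = 0.2
    mass_range: tuple[float, float] = (150.0, 600.0)
    # dilute-end anchor and scale of the salinity score used by degradation
    ec_log10_ref: float = -2.5
    ec_log10_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SurveyConfig.seed is mandatory")
        if abs(sum(self.lake_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("lake_type_mix proportions must sum to 1")
        if set(self.lake_type_mix) - set(LAKE_TYPES):
            raise ValueError("unknown lake type in lake_type_mix")
        for name in ("sulfurization_fraction", "n_enrichment_fraction", "base_rate",
                     "accessory_rate_in", "accessory_rate_out"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(v <= 0 for v in self.pool_sizes.values()):
            raise ValueError("pool sizes must be positive")


# relative inclusion weight of each source class in each lake type; the
# staircase (proglacial > freshwater > saline > hypersaline in total weight)
# makes richness decline along the EC gradient
_TYPE_WEIGHTS: Mapping[str, Mapping[str, float]] = {
    "proglacial": {"fresh": 1.0, "aromatic": 0.35, "highly_unsaturated": 0.75},
    "freshwater": {"fresh": 0.45, "aromatic": 1.0, "highly_unsaturated": 0.9},
    "saline": {"fresh": 0.5, "aromatic": 0.55, "highly_unsaturated": 1.0},
    "hypersaline": {"fresh": 0.4, "aromatic": 0.3, "highly_unsaturated": 0.8},
}

# lake-type environmental regimes: (log10 EC mean, sd) in S/m, (pH mean, sd),
# (temperature mean, sd) in degC, (log10 DIN mean, sd) in umol/L
_ENV_REGIMES = {
    "proglacial": ((-2.2, 0.25), (7.3, 0.15), (0.5, 1.0), (0.5, 0.3)),
    "freshwater": ((-1.3, 0.25), (7.7, 0.20), (3.0, 2.0), (0.0, 0.3)),
    "saline": ((0.3, 0.35), (8.1, 0.20), (3.0, 2.0), (0.5, 0.3)),
    "hypersaline": ((1.3, 0.20), (8.5, 0.15), (4.0, 2.0), (1.5, 0.3)),
}

# flavor of each lake type's accessory/marker formulas: element-ratio windows
# (falling back to the source-class defaults where None) and whether the
# formula is sulfurized. Each flavor occupies a characteristic DBE_AI band:
# proglacial polyol-like oxygenated aliphatics (very negative DBE_AI),
# freshwater terrestrial polyaromatics (high), saline large refractory
# unsaturated backbones (mid), hypersaline sulfurized condensed aromatics
# (very high, S-bearing).
_TYPE_FLAVOR = {
    "proglacial": {
        "source_class": "fresh", "c": (12, 22), "hc": (2.05, 2.45),
        "oc": (0.75, 1.0), "n": (2, 4), "sulfurize": False,
    },
    "freshwater": {
        "source_class": "aromatic", "c": (16, 26), "hc": (0.35, 0.55),
        "oc": (0.02, 0.25), "n": (0, 1), "sulfurize": False,
    },
    "saline": {
        "source_class": "highly_unsaturated", "c": (22, 30), "hc": (1.0, 1.3),
        "oc": (0.3, 0.45), "n": (0, 2), "sulfurize": False,
    },
    "hypersaline": {
        "source_class": "aromatic", "c": (26, 38), "hc": (0.3, 0.5),
        "oc": (0.03, 0.2), "n": (0, 0), "sulfurize": True,
    },
}

_CLASS_PARAMS = {
    # (C range, H/C range, O/C range, N range)
    "fresh": ((8, 26), (1.5, 2.1), (0.1, 0.6), (1, 4)),
    "aromatic": ((10, 30), (0.45, 0.95), (0.05, 0.4), (0, 1)),
    "highly_unsaturated": ((10, 30), (1.0, 1.42), (0.3, 0.85), (0, 2)),
}

_MAX_ATTEMPTS_PER_FORMULA = 3000


def _class_ok(f: MolecularFormula, source_class: str) -> bool:
    cat, _ = classify(f)
    if source_class == "fresh":
        return f.H / f.C >= 1.5 and f.N >= 1 and cat in ("unsaturated", "saturated")
    if source_class == "aromatic":
        return cat == "aromatic"
    return cat == "highly_unsaturated"


def _sample_class_formula(source_class: str, rng: np.random.Generator,
                          cfg: SurveyConfig, taken: set[str],
                          c: tuple[int, int] | None = None,
                          hc: tuple[float, float] | None = None,
                          oc: tuple[float, float] | None = None,
                          n: tuple[int, int] | None = None) -> MolecularFormula:
    (c_lo, c_hi), hc_d, oc_d, (n_lo, n_hi) = _CLASS_PARAMS[source_class]
    c_lo, c_hi = c or (c_lo, c_hi)
    hc = hc or hc_d
    oc = oc or oc_d
    n_lo, n_hi = n or (n_lo, n_hi)
    acfg = AssignmentConfig()
    lo, hi = cfg.mass_range
    for _ in range(_MAX_ATTEMPTS_PER_FORMULA):
        C = int(rng.integers(c_lo, c_hi + 1))
        H = int(round(C * rng.uniform(*hc)))
        O = int(round(C * rng.uniform(*oc)))
        N = int(rng.integers(n_lo, n_hi + 1))
        if (H + N) % 2 == 1:  # keep DBE on the integer grid
            H += 1
        if H < 1:
            continue
        try:
            f = MolecularFormula(C=C, H=H, N=N, O=O)
        except ValueError:
            continue
        if not (lo <= f.mass <= hi):
            continue
        if not apply_chemical_filters([(f, 0.0)], acfg):
            continue
        if not _class_ok(f, source_class) or str(f) in taken:
            continue
        return f
    raise RuntimeError(f"could not sample a distinct {source_class!r} formula")


def _sulfur_analog(f: MolecularFormula) -> MolecularFormula | None:
    """Swap one O for one S; returns None where the swap is infeasible."""
    if f.O < 1 or f.S >= 2:
        return None
    return replace(f, O=f.O - 1, S=f.S + 1)


def _pool_row(f: MolecularFormula, source_class: str, affinity: str | None,
              exclusive: bool) -> dict:
    analog = _sulfur_analog(f)
    return {
        "formula": str(f),
        "source_class": source_class,
        "affinity": affinity,
        "exclusive": exclusive,
        "ai_mod": ai_mod(f),
        "oc": f.O / f.C,
        "has_N": f.N >= 1,
        "category": classify(f)[0],
        "mass": f.mass,
        "mz": ion_mz(f),
        "s_analog": str(analog) if analog is not None else "",
        "s_analog_mz": ion_mz(analog) if analog is not None else np.nan,
    }


def generate_formula_pool(cfg: SurveyConfig, seed: int | None = None) -> pd.DataFrame:
    """Shared formula pool: the three labeled source classes, all distinct.

    Every formula passes the default chemical-plausibility filters, so a
    generated survey can be round-tripped through formula assignment.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    taken: set[str] = set()
    rows = []
    for source_class, size in cfg.pool_sizes.items():
        if source_class not in _CLASS_PARAMS:
            raise ValueError(f"unknown source class {source_class!r}")
        for _ in range(size):
            f = _sample_class_formula(source_class, rng, cfg, taken)
            taken.add(str(f))
            rows.append(_pool_row(f, source_class, None, False))
    return pd.DataFrame(rows)


def _full_pool(cfg: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared pool plus per-type accessory subpools and planted markers."""
    pool = generate_formula_pool(cfg, seed=int(rng.integers(2**31)))
    taken = set(pool["formula"])
    rows = list(pool.to_dict("records"))
    for lake_type in LAKE_TYPES:
        spec = _TYPE_FLAVOR[lake_type]
        for i in range(cfg.accessory_size + cfg.n_exclusive_per_type):
            f = _sample_class_formula(
                spec["source_class"], rng, cfg, taken,
                c=spec["c"], hc=spec["hc"], oc=spec["oc"], n=spec["n"],
            )
            if spec["sulfurize"]:
                analog = _sulfur_analog(f)
                if analog is not None and str(analog) not in taken:
                    f = analog
            taken.add(str(f))
            rows.append(_pool_row(f, spec["source_class"], lake_type, i >= cfg.accessory_size))
    return pd.DataFrame(rows)


def _inclusion_probabilities(pool: pd.DataFrame, env_row: pd.Series,
                             cfg: SurveyConfig) -> np.ndarray:
    lake_type = env_row["lake_type"]
    x = max(0.0, (np.log10(env_row["EC"]) - cfg.ec_log10_ref) / cfg.ec_log10_scale)
    w = np.clip(pool["ai_mod"].to_numpy(float), 0.0, 1.0)
    degrade = np.exp(-cfg.degradation_strength * x * w)
    type_w = pool["source_class"].map(_TYPE_WEIGHTS[lake_type]).to_numpy(float)
    p = cfg.base_rate * type_w * degrade
    # high pH preferentially strips oxygen-rich aromatics
    ph_excess = max(0.0, env_row["pH"] - 7.5)
    hit = (pool["category"] == "aromatic") & (pool["oc"] >= 0.5)
    p = np.where(hit, p * np.exp(-cfg.ph_penalty * ph_excess), p)
    if lake_type == "proglacial":
        p = np.where(pool["has_N"], p * (1.0 + cfg.n_enrichment_fraction), p)
    affinity = pool["affinity"].to_numpy(object)
    accessory = (affinity != None) & ~pool["exclusive"].to_numpy(bool)  # noqa: E711
    p = np.where(accessory & (affinity == lake_type), cfg.accessory_rate_in * degrade, p)
    # sulfurized compounds require sulfide: no leakage outside hypersaline lakes
    out_rate = np.where(affinity == "hypersaline", 0.0, cfg.accessory_rate_out)
    p = np.where(accessory & (affinity != None) & (affinity != lake_type),  # noqa: E711
                 out_rate, p)
    exclusive = pool["exclusive"].to_numpy(bool)
    p = np.where(exclusive, np.where(affinity == lake_type, 1.0, 0.0), p)
    return np.clip(p, 0.0, 1.0)


def generate_lake(pool: pd.DataFrame, env_row: pd.Series, cfg: SurveyConfig,
                  seed: int) -> tuple[PeakList, list[str]]:
    """One lake's peak list plus the canonical formulas actually emitted.

    Formula inclusion is Bernoulli with the mechanism-modified probability;
    retained formulas in hypersaline lakes may be sulfurized; intensities
    are lognormal and observed m/z is the [M-H]- mass with Gaussian ppm
    jitter. Peaks colliding within 0.2 mDa keep only the more intense one.
    """
    rng = np.random.default_rng(seed)
    p = _inclusion_probabilities(pool, env_row, cfg)
    included = rng.random(len(pool)) < p
    if not included.any():
        raise ValueError(f"lake {env_row.name!r}: no formulas retained; parameters infeasible")
    sub = pool.loc[included, ["formula", "mz", "s_analog", "s_analog_mz", "exclusive"]].copy()
    if env_row["lake_type"] == "hypersaline" and cfg.sulfurization_fraction > 0:
        can_swap = (sub["s_analog"] != "") & ~sub["exclusive"].to_numpy(bool)
        swap = can_swap & (rng.random(len(sub)) < cfg.sulfurization_fraction)
        sub.loc[swap, "formula"] = sub.loc[swap, "s_analog"]
        sub.loc[swap, "mz"] = sub.loc[swap, "s_analog_mz"]
        sub = sub.drop_duplicates(subset="formula", keep="first")
    intensity = rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma, len(sub))
    # truncated at 2 sigma: calibrated FT-ICR peak lists have bounded error
    jitter = np.clip(
        rng.normal(0.0, cfg.mass_error_ppm, len(sub)),
        -2.0 * cfg.mass_error_ppm, 2.0 * cfg.mass_error_ppm,
    ) * 1e-6
    mz = sub["mz"].to_numpy(float) * (1.0 + jitter)
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    formulas = sub["formula"].to_numpy(object)[order]
    keep = np.ones(len(mz), dtype=bool)
    for i in range(len(mz) - 1):  # drop the weaker of near-coincident peaks
        if mz[i + 1] - mz[i] < 2e-4:
            keep[i if intensity[i] < intensity[i + 1] else i + 1] = False
    peaks = PeakList(sample_id=str(env_row.name), mz=mz[keep], intensity=intensity[keep])
    return peaks, list(formulas[keep])


def _environment_table(cfg: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    # largest-remainder apportionment of lake types
    quotas = {t: cfg.lake_type_mix.get(t, 0.0) * cfg.n_lakes for t in LAKE_TYPES}
    counts = {t: int(np.floor(q)) for t, q in quotas.items()}
    short = cfg.n_lakes - sum(counts.values())
    for t in sorted(quotas, key=lambda t: quotas[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    rows = []
    i = 0
    for lake_type in LAKE_TYPES:
        (ec_m, ec_s), (ph_m, ph_s), (t_m, t_s), (din_m, din_s) = _ENV_REGIMES[lake_type]
        for _ in range(counts[lake_type]):
            i += 1
            log_ec = rng.normal(ec_m, ec_s)
            rows.append(
                {
                    "lake_id": f"L{i:03d}",
                    "lake_type": lake_type,
                    "EC": 10.0**log_ec,
                    "pH": rng.normal(ph_m, ph_s),
                    "water_temperature": rng.normal(t_m, t_s),
                    "DIN": 10.0 ** rng.normal(din_m, din_s),
                    "DOC": 10.0 ** (0.9 + 0.75 * log_ec + rng.normal(0.0, 0.15)),
                }
            )
    env = pd.DataFrame(rows).set_index("lake_id")
    # coordinates drawn independently of everything else (Soya-Coast-like box)
    env["latitude"] = rng.uniform(-77.5, -68.0, len(env))
    env["longitude"] = rng.uniform(60.0, 105.0, len(env))
    return env


@dataclass
class SurveyResult:
    """A generated survey: peak lists, metadata, and ground truth."""

    peaklists: list[PeakList]
    env: pd.DataFrame
    pool: pd.DataFrame
    included: dict[str, list[str]]  # lake_id -> emitted canonical formulas

    @property
    def lake_types(self) -> pd.Series:
        return self.env["lake_type"]

    @property
    def exclusive_formulas(self) -> dict[str, list[str]]:
        """Planted marker formulas per lake type (exclusive ground truth)."""
        sub = self.pool[self.pool["exclusive"]]
        return {t: sorted(sub.loc[sub["affinity"] == t, "formula"]) for t in LAKE_TYPES}


def generate_survey(cfg: SurveyConfig) -> SurveyResult:
    """Generate a full survey; byte-identical for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    env = _environment_table(cfg, rng)
    pool = _full_pool(cfg, rng)
    peaklists, included = [], {}
    for lake_id, env_row in env.iterrows():
        peaks, emitted = generate_lake(pool, env_row, cfg, seed=int(rng.integers(2**31)))
        peaklists.append(peaks)
        included[lake_id] = emitted
    return SurveyResult(peaklists=peaklists, env=env, pool=pool, included=included)


def write_survey(result: SurveyResult, directory) -> None:
    """Write a survey in the formats the readers consume, plus a truth sidecar."""
    directory = str(directory)
    peak_dir = os.path.join(directory, "peaklists")
    os.makedirs(peak_dir, exist_ok=True)
    for peaks in result.peaklists:
        write_peaklist(peaks, os.path.join(peak_dir, f"{peaks.sample_id}.csv"))
    result.env.reset_index().to_csv(os.path.join(directory, "environment.csv"), index=False)
    truth = {
        "lake_types": result.lake_types.to_dict(),
        "exclusive_formulas": result.exclusive_formulas,
        "included": result.included,
        "pool": result.pool.to_dict("records"),
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
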