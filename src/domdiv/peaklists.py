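"""Peak-list and metadata I/O, blank filtering, and the sample x formula matrix.

Peak lists are delimited text files with ``mz`` and ``intensity`` columns
(one file per sample, negative ionization mode assumed). The sample x
formula matrix collects normalized relative intensities over the union of
assigned formulas, with zeros for absences; its rows are the probability
vectors that every diversity computation consumes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .formulas import AssignedSample, MolecularFormula

__all__ = [
    "PeakList",
    "PeaklistFormat",
    "read_peaklist",
    "write_peaklist",
    "blank_filter",
    "assemble_matrix",
    "normalize_intensities",
    "read_environment",
    "validate_environment",
    "replicate_qc",
    "LAKE_TYPES",
]

logger = logging.getLogger(__name__)

LAKE_TYPES = ("proglacial", "freshwater", "saline", "hypersaline")

#: two peaks closer than this (Da) are considered duplicates of one signal
_DUPLICATE_MZ_DA = 1e-4


@dataclass
class PeakList:
    """Calibrated peaks of one sample: strictly increasing m/z, positive intensities."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    charge_mode: str = "negative"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.charge_mode != "negative":
            raise ValueError(f"unsupported charge mode {self.charge_mode!r}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if len(self.mz) and self.mz[0] <= 0:
            raise ValueError("m/z values must be strictly positive")
        if np.any(self.intensity <= 0):
            bad = int(np.nonzero(self.intensity <= 0)[0][0])
            raise ValueError(
                f"peak {bad} of sample {self.sample_id!r} has non-positive intensity"
            )
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < _DUPLICATE_MZ_DA):
            i = int(np.nonzero(np.diff(self.mz) < _DUPLICATE_MZ_DA)[0][0])
            raise ValueError(
                f"duplicate m/z within 0.1 mDa in sample {self.sample_id!r}: "
                f"{self.mz[i]:.6f} and {self.mz[i + 1]:.6f}"
            )

    def __len__(self) -> int:
        return len(self.mz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


@dataclass(frozen=True)
class PeaklistFormat:
    """Column/delimiter conventions of a peak-list file."""

    sep: str = ","
    mz_col: str = "mz"
    intensity_col: str = "intensity"
    header: bool = True


def read_peaklist(
    path,
    fmt: PeaklistFormat | None = None,
    *,
    sample_id: str | None = None,
    mass_window: tuple[float, float] = (92.0, 1000.0),
) -> PeakList:
    """Read one delimited peak list, dropping rows outside the mass window.

    Raises on empty files, unparseable rows (named by line number) and
    non-positive intensities. The number of out-of-window rows dropped is
    logged at INFO level.
    """
    fmt = fmt or PeaklistFormat()
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        df = pd.read_csv(path, sep=fmt.sep, header=0 if fmt.header else None)
    except pd.errors.EmptyDataError:
        raise ValueError(f"peak list {path} is empty") from None
    if not fmt.header:
        df.columns = [fmt.mz_col, fmt.intensity_col][: len(df.columns)]
    for col in (fmt.mz_col, fmt.intensity_col):
        if col not in df.columns:
            raise ValueError(f"peak list {path} lacks column {col!r}")
    if df.empty:
        raise ValueError(f"peak list {path} has no data rows")
    sub = df[[fmt.mz_col, fmt.intensity_col]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + (2 if fmt.header else 1)
        raise ValueError(f"unparseable row at line {line} of {path}")
    mz = sub[fmt.mz_col].to_numpy(float)
    intensity = sub[fmt.intensity_col].to_numpy(float)
    if np.any(intensity <= 0):
        row = int(np.nonzero(intensity <= 0)[0][0]) + (2 if fmt.header else 1)
        raise ValueError(f"non-positive intensity at line {row} of {path}")
    lo, hi = mass_window
    keep = (mz >= lo) & (mz <= hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d peaks outside [%g, %g] Da", sample_id, n_dropped, lo, hi)
    if not keep.any():
        raise ValueError(f"no peaks of {path} fall inside the mass window {mass_window}")
    return PeakList(sample_id=sample_id, mz=mz[keep], intensity=intensity[keep])


def write_peaklist(peaks: PeakList, path, fmt: PeaklistFormat | None = None) -> None:
    fmt = fmt or PeaklistFormat()
    df = pd.DataFrame({fmt.mz_col: peaks.mz, fmt.intensity_col: peaks.intensity})
    df.to_csv(path, sep=fmt.sep, index=False, header=fmt.header, float_format="%.8f")


def blank_filter(
    sample: PeakList,
    blank: PeakList,
    mz_tol_ppm: float = 0.5,
    ratio_min: float = 5.0,
) -> tuple[PeakList, pd.DataFrame]:
    """Remove sample peaks not sufficiently above a matched process-blank peak.

    A sample peak matched to a blank peak within ``mz_tol_ppm`` is retained
    only if its intensity is at least ``ratio_min`` times the blank
    intensity. Returns the filtered peak list and a report of removed peaks
    (columns ``mz``, ``intensity``, ``blank_mz``, ``blank_intensity``).
    """
    if ratio_min <= 1:
        raise ValueError("ratio_min must exceed 1")
    if len(sample) == 0 or len(blank) == 0:
        raise ValueError("sample and blank peak lists must be nonempty")
    idx = np.searchsorted(blank.mz, sample.mz)
    keep = np.ones(len(sample), dtype=bool)
    removed = []
    for i, mz in enumerate(sample.mz):
        best_j, best_d = -1, np.inf
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < len(blank):
                d = abs(blank.mz[j] - mz)
                if d < best_d:
                    best_j, best_d = j, d
        if best_j >= 0 and best_d <= mz * mz_tol_ppm * 1e-6:
            if sample.intensity[i] < ratio_min * blank.intensity[best_j]:
                keep[i] = False
                removed.append(
                    (mz, sample.intensity[i], blank.mz[best_j], blank.intensity[best_j])
                )
    report = pd.DataFrame(removed, columns=["mz", "intensity", "blank_mz", "blank_intensity"])
    filtered = PeakList(
        sample_id=sample.sample_id, mz=sample.mz[keep], intensity=sample.intensity[keep]
    )
    return filtered, report


def assemble_matrix(samples: Sequence[AssignedSample]) -> pd.DataFrame:
    """Sample x formula intensity matrix over the union of assigned formulas.

    Columns are canonical formula strings ordered by exact mass (ties by
    element counts); a formula absent from a sample gets 0; several peaks of
    one sample mapping to the same formula have their intensities summed.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to assemble a matrix")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among samples")
    series = {s.sample_id: s.intensity_by_formula() for s in samples}
    matrix = pd.DataFrame(series).T.fillna(0.0)
    matrix = matrix.loc[ids]
    order = sorted(matrix.columns, key=lambda s: MolecularFormula.parse(s).sort_key())
    matrix = matrix[order]
    matrix.index.name = "sample_id"
    return matrix


def normalize_intensities(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample row to unit sum (zeros preserved); idempotent."""
    sums = matrix.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(f"sample {zero.idxmax()!r} has zero total intensity")
    return matrix.div(sums, axis=0)


_ENV_REQUIRED = ("lake_type", "latitude", "longitude", "EC", "pH")


def validate_environment(env: pd.DataFrame, require: Iterable[str] = _ENV_REQUIRED) -> pd.DataFrame:
    """Validate per-sample covariates; index must be unique lake/sample ids."""
    if env.index.has_duplicates:
        raise ValueError("duplicate sample ids in environment table")
    missing = [c for c in require if c not in env.columns]
    if missing:
        raise ValueError(f"environment table lacks columns {missing}")
    if "lake_type" in env.columns:
        bad = set(env["lake_type"]) - set(LAKE_TYPES)
        if bad:
            raise ValueError(f"unknown lake types {sorted(bad)}")
    if "latitude" in env.columns and not env["latitude"].between(-90, 90).all():
        raise ValueError("latitude out of [-90, 90]")
    if "longitude" in env.columns and not env["longitude"].between(-180, 180).all():
        raise ValueError("longitude out of [-180, 180]")
    if "EC" in env.columns and not (env["EC"] > 0).all():
        raise ValueError("EC must be positive")
    return env


def read_environment(path, require: Iterable[str] = _ENV_REQUIRED) -> pd.DataFrame:
    """Read the sample metadata table (CSV with a ``lake_id`` column)."""
    env = pd.read_csv(path)
    if "lake_id" not in env.columns:
        raise ValueError("environment table must have a 'lake_id' column")
    env = env.set_index("lake_id")
    return validate_environment(env, require)


def replicate_qc(matrix: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between replicate analyses of one reference sample.

    Replicate runs of the same material should agree to within about 0.05;
    pairs above ``threshold`` are flagged.
    """
    norm = normalize_intensities(matrix)
    d = squareform(pdist(norm.to_numpy(), metric="braycurtis"))
    rows = []
    ids = list(norm.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], d[i, j], d[i, j] > threshold))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bray_curtis", "flagged"])
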