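"""Clustering, ordination, indicator-formula and distance-decay analysis.

Operates on the distance matrices and the environment table: average-linkage
hierarchical clustering with silhouette-based choice of k, non-metric
multidimensional scaling (NMDS), post-hoc fitting of environmental vectors
onto the ordination, Dufrene-Legendre indicator values (IndVal) with a
permutation test and Benjamini-Hochberg adjustment, and Mantel tests of
compositional dissimilarity against great-circle spatial distance and the
Euclidean distance of z-scored environmental variables.

All permutation p-values use the ``(1 + exceedances) / (n_perm + 1)``
estimator, so they are never exactly zero, and every randomized routine
takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_samples
from sklearn.metrics.pairwise import haversine_distances
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment",
    "NMDSResult",
    "MantelResult",
    "hierarchical_cluster",
    "linkage_to_newick",
    "nmds",
    "envfit",
    "indval",
    "mantel",
    "haversine_matrix",
    "env_distance",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class ClusterAssignment:
    """Average-linkage clustering cut at the silhouette-optimal k."""

    labels: pd.Series  # sample_id -> cluster label (1..k)
    k: int
    mean_silhouette: float
    silhouettes: pd.Series
    linkage_matrix: np.ndarray
    silhouette_by_k: pd.Series


def hierarchical_cluster(d: DistanceMatrix, k_range: Sequence[int] | None = None) -> ClusterAssignment:
    """Average-linkage clustering of a distance matrix, k by max mean silhouette.

    The dendrogram is cut at every k in ``k_range`` (default 2..min(10, n-1))
    and the k maximizing the mean silhouette width — computed against the
    original distances, not ordination coordinates — is kept. Ties go to the
    smallest k with a warning. Deterministic given the matrix.
    """
    ids = list(d.ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 samples to cluster")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    Z = linkage(d.condensed_form(), method="average")
    square = d.data
    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            scores[k] = np.nan
            continue
        scores[k] = float(np.mean(silhouette_samples(square, lab, metric="precomputed")))
    by_k = pd.Series(scores)
    if by_k.isna().all():
        warnings.warn(
            "silhouette undefined for every k (degenerate distances); using smallest k",
            stacklevel=2,
        )
        best_k = k_range[0]
    else:
        best = by_k.max()
        tied = [k for k in k_range if np.isfinite(by_k[k]) and by_k[k] >= best - 1e-12]
        if len(tied) > 1:
            warnings.warn(f"silhouette tie among k={tied}; choosing smallest", stacklevel=2)
        best_k = tied[0]
    lab = labels_by_k[best_k]
    if len(np.unique(lab)) >= 2:
        sil = silhouette_samples(square, lab, metric="precomputed")
        mean_sil = float(np.mean(sil))
    else:
        sil = np.full(n, np.nan)
        mean_sil = float("nan")
    return ClusterAssignment(
        labels=pd.Series(lab, index=ids, name="cluster"),
        k=int(best_k),
        mean_silhouette=mean_sil,
        silhouettes=pd.Series(sil, index=ids, name="silhouette"),
        linkage_matrix=Z,
        silhouette_by_k=by_k,
    )


def linkage_to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with branch lengths."""
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return str(ids[i])
        a, b, h, _ = Z[i - n]
        la, lb = int(a), int(b)
        return (
            f"({node(la)}:{heights[i] - heights[la]:.6g},"
            f"{node(lb)}:{heights[i] - heights[lb]:.6g})"
        )

    for idx, (_, _, h, _) in enumerate(Z):
        heights[n + idx] = float(h)
    return node(n + len(Z) - 1) + ";"


@dataclass
class NMDSResult:
    """Non-metric MDS ordination: coordinates and final (normalized) stress."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int


def nmds(d: DistanceMatrix, dims: int = 2, n_starts: int = 8, seed: int = 0,
         max_iter: int = 500) -> NMDSResult:
    """Rank-based NMDS of a distance matrix, best of ``n_starts`` random starts.

    Stress is Kruskal's normalized stress-1; values near 0 indicate a
    faithful low-dimensional embedding. Reproducible given ``seed``.
    """
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        random_state=int(seed),
        max_iter=max_iter,
        normalized_stress=True,
    )
    coords = model.fit_transform(d.data)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("NMDS failed to converge in every start")
    frame = pd.DataFrame(coords, index=list(d.ids),
                         columns=[f"NMDS{i + 1}" for i in range(dims)])
    return NMDSResult(coordinates=frame, stress=float(model.stress_), n_starts=n_starts)


def envfit(
    ordination: pd.DataFrame,
    env: pd.DataFrame,
    vars: Sequence[str],
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Post-hoc least-squares fit of environmental vectors onto an ordination.

    For each variable y, fit y ~ ordination axes; report the direction
    cosines of the fitted vector, r^2 = 1 - SS_res/SS_tot, and a permutation
    p-value from randomly re-pairing y with the ordination rows.
    """
    ids = list(ordination.index)
    missing = [v for v in vars if v not in env.columns]
    if missing:
        raise ValueError(f"environment table lacks variables {missing}")
    env = env.loc[ids]
    X = ordination.to_numpy(float)
    Xc = X - X.mean(axis=0)
    # hat matrix of the centered ordination axes
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    rng = np.random.default_rng(seed)
    n = len(ids)
    rows = {}
    for v in vars:
        y = env[v].to_numpy(float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"variable {v!r} has missing values")
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst <= 0:
            raise ValueError(f"variable {v!r} is constant")
        beta = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ yc
        r2 = float(yc @ H @ yc) / sst
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        perm = np.array([rng.permutation(n) for _ in range(n_perm)])
        Y = yc[perm]  # (n_perm, n)
        r2_perm = np.einsum("ij,jk,ik->i", Y, H, Y) / sst
        p = (1 + int(np.sum(r2_perm >= r2))) / (n_perm + 1)
        rows[v] = {
            **{f"axis{i + 1}": direction[i] for i in range(X.shape[1])},
            "r2": r2,
            "p": p,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def _indval_stats(X: np.ndarray, presence: np.ndarray, groups: np.ndarray,
                  k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-formula A (specificity), B (fidelity) and A*B per cluster."""
    means = np.stack([X[groups == c].mean(axis=0) for c in range(k)])  # (k, F)
    occ = np.stack([presence[groups == c].mean(axis=0) for c in range(k)])
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    return A, occ, A * occ


def indval(
    matrix: pd.DataFrame,
    clusters: pd.Series | "ClusterAssignment",
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dufrene-Legendre indicator values of every formula for its best cluster.

    ``A`` (specificity) is the group mean abundance relative to the sum of
    group means (group-size-unweighted); ``B`` (fidelity) is the fraction of
    the group's samples containing the formula; ``IndVal = max_c A_c B_c``,
    1 when a formula occurs in every sample of exactly one cluster and
    nowhere else. Significance: permutation of cluster labels (statistic =
    max_c IndVal), Benjamini-Hochberg adjusted across formulas.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    labels = labels.loc[matrix.index]
    uniq, groups = np.unique(labels.to_numpy(), return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    counts = np.bincount(groups)
    if counts.min() < 2:
        raise ValueError("every cluster must contain at least 2 samples")
    X = matrix.to_numpy(float)
    presence = (X > 0).astype(float)
    A, B, iv = _indval_stats(X, presence, groups, k)
    best = iv.argmax(axis=0)
    cols = np.arange(X.shape[1])
    stat = iv[best, cols]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        g = rng.permutation(groups)
        _, _, iv_p = _indval_stats(X, presence, g, k)
        exceed += iv_p.max(axis=0) >= stat
    p_raw = (1 + exceed) / (n_perm + 1)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    p_adj = np.maximum(p_adj, p_raw)
    out = pd.DataFrame(
        {
            "best_cluster": uniq[best],
            "A": A[best, cols],
            "B": B[best, cols],
            "indval": stat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj <= alpha,
        },
        index=matrix.columns,
    )
    out.index.name = "formula"
    return out


@dataclass
class MantelResult:
    """Mantel correlation between two distance matrices and its permutation p."""

    r: float
    p: float
    n_perm: int
    alternative: str = "greater"


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation of the two lower triangles.

    Significance by jointly permuting rows and columns of the second matrix;
    one-sided ("greater") by default, matching the hypothesis that the two
    dissimilarities increase together.
    """
    if tuple(d1.ids) != tuple(d2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]
    y2 = d2.data

    def _norm(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        s = np.linalg.norm(v)
        if s == 0:
            raise ValueError("a distance matrix is constant; Mantel r undefined")
        return v / s

    xn = _norm(x)
    r_obs = float(xn @ _norm(y2[iu]))
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_perm[i] = xn @ _norm(y2[np.ix_(perm, perm)][iu])
    if alternative == "greater":
        exceed = np.sum(r_perm >= r_obs)
    elif alternative == "less":
        exceed = np.sum(r_perm <= r_obs)
    else:
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs))
    p = (1 + int(exceed)) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, alternative=alternative)


def haversine_matrix(env: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between samples from latitude/longitude."""
    lat = env["latitude"].to_numpy(float)
    lon = env["longitude"].to_numpy(float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of [-180, 180]")
    radians = np.radians(np.column_stack([lat, lon]))
    d = haversine_distances(radians) * EARTH_RADIUS_KM
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(env.index))


def env_distance(
    env: pd.DataFrame,
    vars: Sequence[str] = ("EC", "pH", "water_temperature", "DIN"),
    transforms: Mapping[str, str] | None = None,
) -> DistanceMatrix:
    """Euclidean distance of z-scored (optionally transformed) variables.

    EC is log10-transformed by default before z-scoring, reflecting its
    orders-of-magnitude range from proglacial to hypersaline lakes.
    """
    if transforms is None:
        transforms = {"EC": "log10"}
    if len(vars) < 1:
        raise ValueError("need at least one variable")
    missing = [v for v in vars if v not in env.columns]
    if missing:
        raise ValueError(f"environment table lacks variables {missing}")
    cols = []
    for v in vars:
        y = env[v].to_numpy(float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"variable {v!r} has missing values")
        t = transforms.get(v)
        if t == "log10":
            if np.any(y <= 0):
                raise ValueError(f"variable {v!r} must be positive for log10")
            y = np.log10(y)
        elif t is not None:
            raise ValueError(f"unknown transform {t!r}")
        sd = y.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"variable {v!r} has zero variance")
        cols.append((y - y.mean()) / sd)
    Z = np.column_stack(cols)
    return DistanceMatrix(squareform(pdist(Z, metric="euclidean")), list(env.index))
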