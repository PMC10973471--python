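"""Hybrid-cell phenotyping: z-score normalization, elbow-selected k-means,
cluster profiles and heatmap export.

Marker intensities of the identified hybrid cells are column-wise z-score
normalized (population SD) over a pooled tissue+blood scope so that
staining-intensity variation among conjugates is brought to one scale; the
number of clusters is chosen by the elbow of the within-cluster sum of
squares curve (maximum second difference); k-means (k-means++, Lloyd, best
of ``n_restarts``) then partitions each compartment's hybrids; cluster
profiles are the per-cluster mean z-scored marker vectors, labeled
T1..Tk / B1..Bk in descending cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

from .errors import ModelIntegrityError, NormalizationError, ParameterError


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

class ZScoreNormalizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with population (ddof=0) standard deviation.

    Zero-variance columns transform to all zeros and are recorded in
    ``zero_variance_columns_`` rather than producing NaNs.  Missing values
    are imputed with the column median when ``missing == "median"``
    (default) or rejected when ``missing == "error"``.

    Attributes
    ----------
    mean_, scale_ : ndarray
        Per-column mean and population SD over the fitted scope.
    zero_variance_columns_ : list
        Names (or indices) of flagged constant columns.
    """

    def __init__(self, missing: str = "median"):
        self.missing = missing

    def fit(self, X, y=None) -> "ZScoreNormalizer":
        arr, cols = self._coerce(X)
        if arr.shape[0] < 2:
            raise NormalizationError("z-scoring needs at least 2 rows in scope")
        self.columns_ = cols
        self.mean_ = np.nanmean(arr, axis=0)
        self.scale_ = np.nanstd(arr, axis=0)  # population SD
        self.zero_variance_columns_ = [
            cols[j] for j in np.flatnonzero(self.scale_ == 0)
        ]
        return self

    def transform(self, X) -> pd.DataFrame:
        arr, cols = self._coerce(X)
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        z = (arr - self.mean_) / scale
        z[:, self.scale_ == 0] = 0.0
        out = pd.DataFrame(z, columns=cols, index=X.index if isinstance(X, pd.DataFrame) else None)
        out.attrs["zero_variance_columns"] = list(self.zero_variance_columns_)
        return out

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            arr = X.to_numpy(dtype=float)
            cols = list(X.columns)
        else:
            arr = np.asarray(X, dtype=float)
            cols = list(range(arr.shape[1]))
        if np.isnan(arr).any():
            if self.missing == "error":
                raise NormalizationError("missing values in normalization scope")
            med = np.nanmedian(arr, axis=0)
            idx = np.where(np.isnan(arr))
            arr = arr.copy()
            arr[idx] = np.take(med, idx[1])
        return arr, cols


def zscore_normalize(matrix: pd.DataFrame, missing: str = "median") -> pd.DataFrame:
    """Z-score ``matrix`` column-wise over its own rows (population SD)."""
    return ZScoreNormalizer(missing=missing).fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# k-means with elbow selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """A fitted k-means partition of one compartment's hybrid cells."""

    k: int
    assignments: np.ndarray  # per-cell cluster index 0..k-1
    centroids: np.ndarray  # (k, n_markers)
    wcss: float
    seed: int | None
    compartment: str = "tissue"
    cluster_labels: list = field(default_factory=list)  # e.g. ["T1", "T2", ...]

    def __post_init__(self) -> None:
        if self.wcss < 0:
            raise ModelIntegrityError("WCSS must be >= 0")
        counts = np.bincount(self.assignments, minlength=self.k)
        if (counts == 0).any():
            raise ModelIntegrityError("empty cluster in fitted model")


def compute_wcss(X: np.ndarray, assignments: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squares of a given partition."""
    X = np.asarray(X, dtype=float)
    return float(((X - centroids[assignments]) ** 2).sum())


def _fit_kmeans(X: np.ndarray, k: int, seed, n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    return km.fit(X)


def kmeans_cluster(
    X,
    k: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    compartment: str = "tissue",
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means from k-means++ initialization."""
    arr = np.asarray(X, dtype=float)
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > arr.shape[0]:
        raise ParameterError(f"k={k} exceeds n={arr.shape[0]} points")
    km = _fit_kmeans(arr, k, seed, n_restarts)
    prefix = "T" if compartment == "tissue" else "B"
    order = _size_order(km.labels_, k)
    labels = [f"{prefix}{np.flatnonzero(order == c)[0] + 1}" for c in range(k)]
    return ClusterModel(
        k=k,
        assignments=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        wcss=float(km.inertia_),
        seed=seed,
        compartment=compartment,
        cluster_labels=labels,
    )


def _size_order(assignments: np.ndarray, k: int) -> np.ndarray:
    """Cluster ids ordered by descending size (ties: ascending id)."""
    counts = np.bincount(assignments, minlength=k)
    return np.array(sorted(range(k), key=lambda c: (-counts[c], c)))


def wcss_curve(X, k_range, seed: int | None = 0, n_restarts: int = 10) -> dict:
    """WCSS(k) for each k in ``k_range`` (best of restarts per k)."""
    arr = np.asarray(X, dtype=float)
    return {
        int(k): float(_fit_kmeans(arr, int(k), seed, n_restarts).inertia_)
        for k in k_range
    }


def select_k_elbow(
    X,
    k_range=range(1, 9),
    seed: int | None = 0,
    n_restarts: int = 10,
    curve: dict | None = None,
) -> int:
    """Elbow selection: the interior k maximizing the second difference
    WCSS(k-1) - 2*WCSS(k) + WCSS(k+1); ties resolve to the smallest k.

    ``k_range`` must hold at least 3 consecutive integers within [1, n].
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ParameterError("k_range must contain at least 3 values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ParameterError("k_range must be consecutive integers")
    arr = np.asarray(X, dtype=float)
    if ks[0] < 1 or ks[-1] > arr.shape[0]:
        raise ParameterError(f"k_range {ks[0]}..{ks[-1]} outside [1, n={arr.shape[0]}]")
    w = curve if curve is not None else wcss_curve(arr, ks, seed, n_restarts)
    best_k, best_d2 = None, -np.inf
    for k in ks[1:-1]:
        d2 = w[k - 1] - 2 * w[k] + w[k + 1]
        if d2 > best_d2 + 1e-12:
            best_k, best_d2 = k, d2
    return int(best_k)


class ElbowKMeans(BaseEstimator, ClusterMixin):
    """K-means with the cluster count chosen by the WCSS elbow.

    Parameters
    ----------
    k : int, optional
        Fixed cluster count; when None, selected by :func:`select_k_elbow`
        over ``k_range``.
    k_range : iterable of int
        Candidate ks (consecutive; ends are never selected).
    n_restarts : int
        k-means++ restarts per fit (best WCSS wins).
    random_state : int, optional
        Seed for all restarts; fixed seeds make fits reproducible.
    compartment : {"tissue", "blood"}
        Determines the T/B cluster-label prefix.

    Attributes
    ----------
    k_ : int selected or fixed cluster count
    labels_ : per-cell cluster indices
    cluster_centers_ : (k, n_markers) centroids
    wcss_ : within-cluster sum of squares of the fit
    wcss_curve_ : dict of WCSS(k) when the elbow ran
    model_ : the equivalent :class:`ClusterModel`
    """

    def __init__(
        self,
        k: int | None = None,
        k_range=range(1, 9),
        n_restarts: int = 10,
        random_state: int | None = 0,
        compartment: str = "tissue",
    ):
        self.k = k
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.compartment = compartment

    def fit(self, X, y=None) -> "ElbowKMeans":
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if self.k is None:
            ks = [k for k in self.k_range if k <= arr.shape[0]]
            self.wcss_curve_ = wcss_curve(arr, ks, self.random_state, self.n_restarts)
            self.k_ = select_k_elbow(arr, ks, curve=self.wcss_curve_)
        else:
            self.k_ = int(self.k)
            self.wcss_curve_ = None
        self.model_ = kmeans_cluster(
            arr, self.k_, self.random_state, self.n_restarts, self.compartment
        )
        self.labels_ = self.model_.assignments
        self.cluster_centers_ = self.model_.centroids
        self.wcss_ = self.model_.wcss
        return self

    def predict(self, X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        d = ((arr[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


# ---------------------------------------------------------------------------
# profiles and heatmap
# ---------------------------------------------------------------------------

def cluster_profiles(model: ClusterModel, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster mean z-scored marker vectors.

    Returns (profiles, sizes): profiles indexed T1..Tk / B1..Bk by
    descending cluster size (deterministic labeling), columns = markers.
    """
    if len(model.assignments) != len(X):
        raise ModelIntegrityError("assignments do not align with the matrix rows")
    arr = X.to_numpy(dtype=float)
    counts = np.bincount(model.assignments, minlength=model.k)
    if (counts == 0).any():
        raise ModelIntegrityError("empty cluster")
    prefix = "T" if model.compartment == "tissue" else "B"
    order = _size_order(model.assignments, model.k)
    rows, names, sizes = [], [], []
    for rank, c in enumerate(order, start=1):
        rows.append(arr[model.assignments == c].mean(axis=0))
        names.append(f"{prefix}{rank}")
        sizes.append(int(counts[c]))
    profiles = pd.DataFrame(rows, index=names, columns=list(X.columns))
    return profiles, pd.Series(sizes, index=names, name="n_cells")


def export_heatmap(
    X: pd.DataFrame,
    model: ClusterModel,
    png_path=None,
    csv_path=None,
) -> pd.DataFrame | None:
    """Cells-as-columns heatmap grouped by cluster, markers as rows,
    diverging color scale centered at 0; writes the ordered matrix as CSV.

    Returns the ordered matrix (markers x cells), or None on an empty
    hybrid set (a warning is emitted and nothing is written)."""
    import warnings

    if len(X) == 0:
        warnings.warn("empty hybrid set: heatmap not written", stacklevel=2)
        return None
    order = _size_order(model.assignments, model.k)
    col_order = np.concatenate([np.flatnonzero(model.assignments == c) for c in order])
    ordered = X.iloc[col_order].T  # markers x cells
    ordered.columns = [str(c) for c in ordered.columns]
    if csv_path is not None:
        ordered.to_csv(csv_path)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmax = float(np.abs(ordered.to_numpy()).max()) or 1.0
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(ordered.index)), labels=list(ordered.index), fontsize=6)
        ax.set_xlabel("hybrid cells (grouped by cluster)")
        fig.colorbar(im, ax=ax, label="z-score")
        # cluster boundaries
        sizes = [int((model.assignments == c).sum()) for c in order]
        edge = 0
        for s in sizes[:-1]:
            edge += s
            ax.axvline(edge - 0.5, color="k", lw=0.5)
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return ordered
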