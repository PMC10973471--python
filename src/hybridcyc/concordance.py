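"""Tissue-blood cluster concordance by Pearson correlation.

Each tissue hybrid cluster's profile (mean z-scored marker vector) is
correlated with each blood cluster's profile over the marker dimension,
giving a T x B Pearson matrix; pairs above a configurable ``r_min`` are
reported as conserved cross-compartment phenotypes, with the full matrix
always available so the cutoff hides nothing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, DimensionError


def pearson_r(a, b) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3).

    A constant vector makes the correlation undefined: returns NaN with a
    warning rather than raising, so matrix assembly can continue."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError("pearson_r needs two equal-length 1-D vectors")
    if len(a) < 3:
        raise DimensionError("pearson_r needs length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant vector: correlation undefined (NaN)", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cluster_correlation_matrix(
    tissue_profiles: pd.DataFrame, blood_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise Pearson r between every tissue and blood cluster profile.

    Rows = tissue cluster ids, columns = blood cluster ids.  Profiles must
    share an identical marker order."""
    if list(tissue_profiles.columns) != list(blood_profiles.columns):
        raise AlignmentError("tissue and blood profiles disagree on marker order")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = np.array(
            [
                [pearson_r(trow, brow) for _, brow in blood_profiles.iterrows()]
                for _, trow in tissue_profiles.iterrows()
            ]
        )
    return pd.DataFrame(values, index=tissue_profiles.index, columns=blood_profiles.index)


def conserved_pairs(matrix: pd.DataFrame, r_min: float = 0.7) -> pd.DataFrame:
    """(T, B, r) pairs with r >= r_min, sorted descending by r.

    Ties keep row-major (T then B) order for determinism."""
    rows = []
    for t in matrix.index:
        for b in matrix.columns:
            r = matrix.loc[t, b]
            if np.isfinite(r) and r >= r_min:
                rows.append({"tissue_cluster": t, "blood_cluster": b, "r": float(r)})
    out = pd.DataFrame(rows, columns=["tissue_cluster", "blood_cluster", "r"])
    if len(out):
        out = out.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)
    return out


def export_correlation_heatmap(matrix: pd.DataFrame, png_path) -> None:
    """Corrplot-style heatmap of the tissue x blood correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), labels=list(matrix.columns))
    ax.set_yticks(range(len(matrix.index)), labels=list(matrix.index))
    ax.set_xlabel("blood clusters")
    ax.set_ylabel("tissue clusters")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
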