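"""Signal-to-background validation of staining conditions.

Each antibody-oligonucleotide conjugate is validated by comparing staining
conditions (indirect immunofluorescence, conjugate + secondary antibody,
conjugate + imaging strand) against controls (UV-cleaved, imaging strand
only).  Two normalization modes mirror the study design:

* tissue mode — one representative ROI per condition; the mean intensity of
  the positive cells under each condition is divided by the mean under the
  imaging-strand-only control.
* blood mode — a two-population model (cancer cells spiked into PBMCs,
  distinguished by size); per ROI the positive-population mean is divided
  by the negative-population mean, then the default three ROI ratios are
  averaged.  Markers staining both populations (e.g. CD44, aSMA) are
  instead normalized to imaging-strand-only cells ("dual" mode).

All ratios are scale-invariant: multiplying every intensity in an ROI set
by a constant leaves them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from skimage.filters import threshold_otsu

from .errors import (
    ControlMissingError,
    DivisionDegenerateError,
    PopulationMissingError,
)
from .layout import RoundLayout, default_layout
from .synthetic import VALIDATION_CONDITIONS, marker_column


@dataclass
class SBResult:
    """One marker x condition signal-to-background ratio."""

    marker: str
    condition: str
    mode: str  # "tissue" | "blood"
    ratio: float
    n_rois: int
    per_roi_ratios: list = field(default_factory=list)


def _compartment_values(table: pd.DataFrame, marker: str, compartment: str) -> np.ndarray:
    return table[marker_column(marker, compartment)].to_numpy(dtype=float)


def positive_by_threshold(
    values: np.ndarray, control_values: np.ndarray, k: float = 3.0
) -> np.ndarray:
    """Numeric positivity: intensity strictly above control mean + k*SD."""
    thr = float(np.mean(control_values)) + k * float(np.std(control_values))
    return np.asarray(values) > thr


def sb_tissue(
    tables_by_condition: dict,
    marker: str,
    compartment: str = "whole_cell",
    layout: RoundLayout | None = None,
    control_condition: str = "is_only",
    positive_masks: dict | None = None,
) -> dict:
    """Tissue-mode S:B for every supplied condition.

    ratio(condition) = mean intensity of that condition's positive cells
    divided by the mean over the imaging-strand-only control's positive-
    pattern cells (single representative ROI per condition).  Positive cells
    come from ``positive_masks`` when given, else from a ``population_label``
    / truth ``is_positive`` column, else all cells (uniform ROI).
    """
    layout = layout or default_layout()
    if control_condition not in tables_by_condition:
        raise ControlMissingError(f"{control_condition} control ROI missing")

    def pos_values(condition: str) -> np.ndarray:
        t = tables_by_condition[condition]
        vals = _compartment_values(t, marker, compartment)
        if positive_masks and condition in positive_masks:
            mask = np.asarray(positive_masks[condition], dtype=bool)
        elif "is_positive" in t.columns and t["is_positive"].any():
            mask = t["is_positive"].to_numpy(dtype=bool)
        else:  # controls: anticipated-pattern cells = all cells of the ROI
            mask = np.ones(len(t), dtype=bool)
        return vals[mask]

    control_mean = float(np.mean(pos_values(control_condition)))
    if control_mean == 0:
        raise DivisionDegenerateError("imaging-strand-only control mean is zero")
    out = {}
    for condition in tables_by_condition:
        ratio = float(np.mean(pos_values(condition))) / control_mean
        out[condition] = SBResult(marker, condition, "tissue", ratio, n_rois=1, per_roi_ratios=[ratio])
    return out


def sb_blood(
    roi_tables: list,
    marker: str,
    positive_population: str,
    compartment: str | None = None,
    layout: RoundLayout | None = None,
    condition: str = "aboligo_is",
) -> SBResult:
    """Blood-model S:B: positive-population mean over negative-population
    mean per ROI, averaged over the (default three) ROIs.

    The compartment defaults to the marker's phenotyping compartment (it is
    evaluated depending on the protein's subcellular localization).
    """
    layout = layout or default_layout()
    compartment = compartment or layout.compartment_of(marker)
    if positive_population not in ("cancer", "pbmc"):
        raise PopulationMissingError(
            "blood mode needs a single positive population (use sb_blood_dual for both)"
        )
    negative = "pbmc" if positive_population == "cancer" else "cancer"
    ratios = []
    for i, t in enumerate(roi_tables):
        pop = t["population_label"].to_numpy()
        vals = _compartment_values(t, marker, compartment)
        pos, neg = vals[pop == positive_population], vals[pop == negative]
        if len(pos) == 0 or len(neg) == 0:
            raise PopulationMissingError(f"ROI {i} lacks a {'positive' if not len(pos) else 'negative'} population")
        neg_mean = float(np.mean(neg))
        if neg_mean == 0:
            raise DivisionDegenerateError(f"ROI {i} negative-population mean is zero")
        ratios.append(float(np.mean(pos)) / neg_mean)
    return SBResult(marker, condition, "blood", float(np.mean(ratios)), len(ratios), ratios)


def sb_blood_dual(
    roi_tables: list,
    is_only_tables: list,
    marker: str,
    compartment: str | None = None,
    layout: RoundLayout | None = None,
    condition: str = "aboligo_is",
) -> SBResult:
    """Dual-staining blood S:B for markers staining both populations:
    mean of all stained cells over the mean of imaging-strand-only cells,
    per paired ROI, averaged."""
    layout = layout or default_layout()
    compartment = compartment or layout.compartment_of(marker)
    if not is_only_tables:
        raise ControlMissingError("imaging-strand-only ROIs missing")
    ratios = []
    for i, (stained, control) in enumerate(zip(roi_tables, is_only_tables)):
        ctrl_mean = float(np.mean(_compartment_values(control, marker, compartment)))
        if ctrl_mean == 0:
            raise DivisionDegenerateError(f"ROI {i} imaging-strand-only mean is zero")
        ratios.append(float(np.mean(_compartment_values(stained, marker, compartment))) / ctrl_mean)
    return SBResult(marker, condition, "blood", float(np.mean(ratios)), len(ratios), ratios)


class SizeClassifier(BaseEstimator, ClassifierMixin):
    """Cancer-vs-PBMC classification by cell size.

    Cancer cells in the blood model are notably larger than PBMCs, so a
    single area threshold separates them.  With ``threshold=None`` the
    threshold is fitted by an Otsu split of the log-area distribution
    (cell sizes are multiplicative, so the split is found on the log scale
    and reported in area units); a degenerate (unimodal/constant)
    distribution yields a warning and an all-PBMC labeling.

    Attributes
    ----------
    threshold_ : float or None
        Fitted area threshold (px^2); None when degenerate.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y=None) -> "SizeClassifier":
        areas = self._areas(X)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            return self
        try:
            if np.ptp(areas) == 0:
                raise ValueError("constant areas")
            self.threshold_ = float(np.exp(threshold_otsu(np.log(np.asarray(areas, dtype=float)))))
        except ValueError:
            warnings.warn(
                "degenerate area distribution: labeling all cells pbmc", stacklevel=2
            )
            self.threshold_ = None
        return self

    def predict(self, X) -> np.ndarray:
        areas = self._areas(X)
        if getattr(self, "threshold_", None) is None:
            return np.array(["pbmc"] * len(areas))
        return np.where(areas > self.threshold_, "cancer", "pbmc")

    @staticmethod
    def _areas(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X["area"].to_numpy(dtype=float)
        return np.asarray(X, dtype=float).ravel()


def classify_population_by_size(cells: pd.DataFrame, size_threshold: float | None = None) -> np.ndarray:
    """Label each cell ``cancer`` or ``pbmc`` by area (Otsu split default)."""
    clf = SizeClassifier(threshold=size_threshold).fit(cells)
    return clf.predict(cells)


def validate_panel_blood(
    specimens_by_condition: dict,
    marker: str,
    positive_population: str,
    layout: RoundLayout | None = None,
) -> dict:
    """Convenience: blood-model S:B of one marker for every condition.

    ``specimens_by_condition[condition]`` is a list of ROI tables.  Markers
    staining both populations use dual normalization against the paired
    imaging-strand-only ROIs; ``none``-type markers fall back to the
    cancer-positive convention (their ratio sits at ~1 by construction).
    """
    layout = layout or default_layout()
    out = {}
    for condition in specimens_by_condition:
        if condition not in VALIDATION_CONDITIONS:
            raise ControlMissingError(f"unknown condition {condition!r}")
        rois = specimens_by_condition[condition]
        if positive_population == "both":
            out[condition] = sb_blood_dual(
                rois, specimens_by_condition["is_only"], marker, layout=layout, condition=condition
            )
        else:
            pop = positive_population if positive_population in ("cancer", "pbmc") else "cancer"
            out[condition] = sb_blood(rois, marker, pop, layout=layout, condition=condition)
    return out
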