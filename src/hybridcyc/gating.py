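"""Marker positivity gating and hybrid-cell identification.

A hybrid cell co-expresses the pan-leukocyte marker CD45 and at least one
marker of the epithelial cocktail (ECAD, EpCAM, panCK).  Positivity of a
marker is a whole-cell mean intensity strictly above a per-marker threshold
derived by normalizing to an unstained control — by default the control
mean plus three standard deviations (quantile and absolute rules are
available).  :class:`MarkerGater` follows the scikit-learn estimator
protocol: ``fit`` on the unstained-control table derives the thresholds,
``predict`` returns the boolean positivity matrix for any specimen table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .errors import EmptySpecimenError, GatingError, InsufficientControlError
from .layout import EPITHELIAL_COCKTAIL, GATING_MARKERS, LEUKOCYTE_MARKER, RoundLayout, default_layout
from .synthetic import marker_column

GATE_RULES = ("mean_plus_ksd", "quantile", "absolute")


@dataclass
class GateThresholds:
    """Per-marker positivity cutoffs and their provenance."""

    thresholds: dict
    rule: str = "mean_plus_ksd"
    control_n: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, t in self.thresholds.items():
            if not np.isfinite(t) or t < 0:
                raise GatingError(f"threshold for {m} must be finite and >= 0, got {t}")

    def require(self, markers) -> None:
        missing = [m for m in markers if m not in self.thresholds]
        if missing:
            raise GatingError(f"no threshold for markers: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "rule": self.rule,
                    "control_n": int(self.control_n),
                    "params": dict(self.params),
                    "thresholds": {m: float(t) for m, t in self.thresholds.items()},
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "GateThresholds":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            thresholds=d["thresholds"],
            rule=d.get("rule", "absolute"),
            control_n=d.get("control_n", 0),
            params=d.get("params", {}),
        )


class MarkerGater(BaseEstimator):
    """Derive positivity thresholds from an unstained control and call
    marker positivity per cell.

    Parameters
    ----------
    rule : {"mean_plus_ksd", "quantile", "absolute"}
        Threshold rule.  ``mean_plus_ksd`` (default): control mean + k*SD
        per marker.  ``quantile``: the control's ``quantile`` per marker.
        ``absolute``: fixed ``thresholds`` mapping, no control needed.
    k : float
        SD multiplier for ``mean_plus_ksd`` (default 3).
    quantile : float
        Control quantile for the ``quantile`` rule.
    thresholds : dict, optional
        Marker -> cutoff for the ``absolute`` rule.
    markers : sequence, optional
        Markers to gate; defaults to the four gating markers
        (CD45 + epithelial cocktail).
    compartment : str
        Compartment of the gated mean; positivity is defined on the
        whole-cell average regardless of a marker's phenotyping compartment.
    min_control_cells : int
        ``fit`` refuses smaller controls unless ``allow_small_control``.

    Attributes
    ----------
    thresholds_ : GateThresholds
        Fitted per-marker cutoffs.
    """

    def __init__(
        self,
        rule: str = "mean_plus_ksd",
        k: float = 3.0,
        quantile: float = 0.995,
        thresholds: dict | None = None,
        markers=None,
        compartment: str = "whole_cell",
        min_control_cells: int = 10,
        allow_small_control: bool = False,
    ):
        self.rule = rule
        self.k = k
        self.quantile = quantile
        self.thresholds = thresholds
        self.markers = markers
        self.compartment = compartment
        self.min_control_cells = min_control_cells
        self.allow_small_control = allow_small_control

    def _marker_list(self, table: pd.DataFrame | None = None) -> list:
        if self.markers is not None:
            return list(self.markers)
        return list(GATING_MARKERS)

    def fit(self, control_table: pd.DataFrame | None = None, y=None) -> "MarkerGater":
        if self.rule not in GATE_RULES:
            raise GatingError(f"unknown rule {self.rule!r}")
        markers = self._marker_list(control_table)
        if self.rule == "absolute":
            if not self.thresholds:
                raise GatingError("absolute rule needs a thresholds mapping")
            thr = {m: float(self.thresholds[m]) for m in self.thresholds}
            self.thresholds_ = GateThresholds(thr, rule="absolute", control_n=0)
            return self
        if control_table is None or control_table.empty:
            raise InsufficientControlError("control table is empty")
        n = len(control_table)
        if n < self.min_control_cells and not self.allow_small_control:
            raise InsufficientControlError(
                f"{n} control cells < required {self.min_control_cells} "
                "(set allow_small_control=True to override)"
            )
        thr = {}
        for m in markers:
            col = marker_column(m, self.compartment)
            if col not in control_table.columns:
                raise GatingError(f"control table lacks column {col}")
            vals = control_table[col].to_numpy(dtype=float)
            if self.rule == "mean_plus_ksd":
                thr[m] = float(np.mean(vals) + self.k * np.std(vals))
            else:
                thr[m] = float(np.quantile(vals, self.quantile))
        self.thresholds_ = GateThresholds(
            thr, rule=self.rule, control_n=n,
            params={"k": self.k} if self.rule == "mean_plus_ksd" else {"quantile": self.quantile},
        )
        return self

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Boolean positivity matrix (cells x markers), strict inequality.

        Missing intensities produce a negative call and are flagged in the
        frame's ``attrs['missing_flagged']``."""
        if not hasattr(self, "thresholds_"):
            raise GatingError("gater is not fitted")
        return call_positive(table, self.thresholds_, self.compartment)


def derive_thresholds(
    control_table: pd.DataFrame,
    rule: str = "mean_plus_ksd",
    k: float = 3.0,
    quantile: float = 0.995,
    markers=None,
    compartment: str = "whole_cell",
    **kwargs,
) -> GateThresholds:
    """Functional wrapper over :meth:`MarkerGater.fit`."""
    gater = MarkerGater(
        rule=rule, k=k, quantile=quantile, markers=markers, compartment=compartment, **kwargs
    )
    return gater.fit(control_table).thresholds_


def call_positive(
    table: pd.DataFrame, thresholds: GateThresholds, compartment: str = "whole_cell"
) -> pd.DataFrame:
    """Per-cell, per-marker positivity: value strictly above the threshold.

    A missing intensity yields a negative call; the (cell, marker) pairs so
    flagged are listed in ``result.attrs['missing_flagged']``."""
    calls = {}
    missing_flagged = []
    for m, thr in thresholds.thresholds.items():
        col = marker_column(m, compartment)
        if col not in table.columns:
            raise GatingError(f"table lacks column {col} for marker {m}")
        vals = table[col].to_numpy(dtype=float)
        isna = ~np.isfinite(vals)
        calls[m] = np.where(isna, False, vals > thr)
        for i in np.flatnonzero(isna):
            missing_flagged.append((table["cell_id"].iloc[i], m))
    out = pd.DataFrame(calls, index=table.index)
    out.insert(0, "cell_id", table["cell_id"].to_numpy())
    out.attrs["missing_flagged"] = missing_flagged
    return out


def identify_hybrids(
    calls: pd.DataFrame,
    leukocyte: str = LEUKOCYTE_MARKER,
    epithelial=EPITHELIAL_COCKTAIL,
) -> pd.DataFrame:
    """Hybrid call per cell: positive for CD45 AND >= 1 epithelial-cocktail
    marker.  Records the positive epithelial subset for provenance."""
    if leukocyte not in calls.columns:
        raise GatingError(f"calls lack the {leukocyte} column")
    present = [m for m in epithelial if m in calls.columns]
    if not present:
        raise GatingError(f"calls lack every epithelial-cocktail column {epithelial}")
    epi = calls[present].to_numpy(dtype=bool)
    cd45 = calls[leukocyte].to_numpy(dtype=bool)
    is_hybrid = cd45 & epi.any(axis=1)
    epi_sets = [
        "|".join(m for m, on in zip(present, row) if on) for row in epi
    ]
    out = pd.DataFrame(
        {
            "cell_id": calls["cell_id"].to_numpy(),
            "is_hybrid": is_hybrid,
            "epithelial_positive_set": epi_sets,
        },
        index=calls.index,
    )
    return out


def summarize_counts(hybrid_calls: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Hybrid counts and percentages per specimen.

    The denominator is exactly the post-QC cell count of the supplied
    table; ``percentage = 100 * n_hybrids / n_total``.
    """
    if table.empty:
        raise EmptySpecimenError("cannot summarize an empty specimen")
    merged = table[["cell_id", "specimen_id", "specimen_type"]].merge(
        hybrid_calls[["cell_id", "is_hybrid"]], on="cell_id", how="left"
    )
    merged["is_hybrid"] = merged["is_hybrid"].fillna(False)
    rows = []
    for (sid, stype), grp in merged.groupby(["specimen_id", "specimen_type"], sort=True):
        n_total = int(len(grp))
        n_hybrids = int(grp["is_hybrid"].sum())
        rows.append(
            {
                "specimen_id": sid,
                "specimen_type": stype,
                "n_hybrids": n_hybrids,
                "n_total": n_total,
                "percentage": 100.0 * n_hybrids / n_total,
            }
        )
    return pd.DataFrame(rows)
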