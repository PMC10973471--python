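"""Per-cell intensity extraction and the exclusion rules applied before gating.

For every cell and marker the arithmetic mean pixel intensity is extracted
in three compartments (whole cell, nucleus, cytoplasm) from the registered
stacks, together with the whole-cell mean on the round-0 background channel
(per-cell autofluorescence).  Cells are then excluded for falling in an
exclusion region (tissue edges, imaging artifacts), for high round-0
autofluorescence, or for implausible segmentation (area bounds, low
solidity); cells touching a brighter neighbor are flagged for optional
exclusion rather than dropped.  Every removal carries a reason code in the
returned log so that rows_out = rows_in - removals is auditable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import DimensionError, LayoutError
from .layout import RoundLayout, default_layout
from .segmentation import LabelMasks, mask_solidity
from .synthetic import marker_column


def _label_means(image: np.ndarray, labels: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Mean of ``image`` over each label in ``index``; NaN where a label has
    no pixels (e.g. an empty cytoplasm)."""
    present = np.unique(labels[labels > 0])
    out = np.full(len(index), np.nan)
    if len(present) == 0:
        return out
    means = ndi.mean(image, labels=labels, index=present)
    lookup = dict(zip(present.tolist(), np.atleast_1d(means).tolist()))
    for i, lab in enumerate(index):
        if lab in lookup:
            out[i] = lookup[lab]
    return out


def extract_features(
    stacks: dict,
    channels: dict,
    masks: LabelMasks,
    layout: RoundLayout | None = None,
    specimen_id: str = "S1",
    specimen_type: str = "tissue",
) -> pd.DataFrame:
    """Build the single-cell table from registered stacks and label masks.

    One row per cell: centroid, area, per-marker compartment means, and the
    round-0 background mean.  An empty cytoplasm yields a missing value,
    never zero.
    """
    layout = layout or default_layout()
    masks.validate()
    index = masks.labels
    n = len(index)

    centroids = ndi.center_of_mass(masks.cell > 0, masks.cell, index) if n else []
    areas = ndi.sum_labels(np.ones_like(masks.cell), masks.cell, index) if n else []
    table = pd.DataFrame(
        {
            "cell_id": [f"{specimen_id}_c{int(lab):06d}" for lab in index],
            "label": index,
            "specimen_id": specimen_id,
            "specimen_type": specimen_type,
            "x": [c[1] for c in centroids],
            "y": [c[0] for c in centroids],
            "area": np.asarray(areas, dtype=float),
        }
    )

    comp_masks = {
        "whole_cell": masks.cell,
        "nucleus": masks.nucleus,
        "cytoplasm": masks.cytoplasm,
    }
    for m in layout.markers:
        if m.round not in stacks:
            raise LayoutError(f"round {m.round} missing from stacks")
        chans = channels[m.round]
        if m.channel not in chans:
            raise LayoutError(f"channel {m.channel} (marker {m.name}) missing from round {m.round}")
        img = np.asarray(stacks[m.round][chans.index(m.channel)], dtype=float)
        if img.shape != masks.cell.shape:
            raise DimensionError("stack and mask shapes differ")
        for comp, lab in comp_masks.items():
            table[marker_column(m.name, comp)] = _label_means(img, lab, index)

    r0 = layout.background_round
    if r0 in stacks and layout.background_channel in channels.get(r0, []):
        bg = np.asarray(stacks[r0][channels[r0].index(layout.background_channel)], dtype=float)
        table["round0_mean"] = _label_means(bg, masks.cell, index)
    else:
        table["round0_mean"] = np.nan
    dapi_ref = layout.rounds[0]
    dapi_img = np.asarray(
        stacks[dapi_ref][channels[dapi_ref].index(layout.nuclear_channel)], dtype=float
    )
    table["dapi_mean"] = _label_means(dapi_img, masks.nucleus, index)
    table["qc_flags"] = ""
    return table


# ---------------------------------------------------------------------------
# exclusion filters — each returns (filtered_table, log)
# ---------------------------------------------------------------------------

def _make_log(table: pd.DataFrame, removed: pd.Series, reason: str, **extra) -> pd.DataFrame:
    log = pd.DataFrame({"cell_id": table.loc[removed, "cell_id"], "reason": reason})
    for k, v in extra.items():
        log[k] = v
    return log.reset_index(drop=True)


def apply_exclusion_mask(
    table: pd.DataFrame, exclusion: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells whose centroid falls inside an excluded (True) region."""
    exclusion = np.asarray(exclusion, dtype=bool)
    ys = np.clip(np.rint(table["y"].to_numpy(dtype=float)).astype(int), 0, exclusion.shape[0] - 1)
    xs = np.clip(np.rint(table["x"].to_numpy(dtype=float)).astype(int), 0, exclusion.shape[1] - 1)
    removed = pd.Series(exclusion[ys, xs], index=table.index)
    log = _make_log(table, removed, "excluded_region")
    return table.loc[~removed].reset_index(drop=True), log


def filter_autofluorescence(
    table: pd.DataFrame,
    quantile: float = 0.99,
    cutoff: float | None = None,
    per_specimen: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cells with high round-0 autofluorescence.

    Default rule: strictly greater than the per-specimen ``quantile``
    (99th percentile) of ``round0_mean``; an ``absolute`` cutoff overrides
    the quantile.  The applied cutoff(s) are recorded in the log — reuse
    them for an exactly idempotent re-application (a quantile recomputed on
    an already-filtered table necessarily shifts).
    """
    if table.empty:
        return table.copy(), pd.DataFrame(columns=["cell_id", "reason", "cutoff"])
    r0 = table["round0_mean"].to_numpy(dtype=float)
    if cutoff is not None:
        cut = np.full(len(table), float(cutoff))
    elif per_specimen:
        cut = table.groupby("specimen_id")["round0_mean"].transform(
            lambda s: s.quantile(quantile)
        ).to_numpy(dtype=float)
    else:
        cut = np.full(len(table), float(np.quantile(r0, quantile)))
    removed = pd.Series(r0 > cut, index=table.index)
    log = _make_log(table, removed, "high_autofluorescence", cutoff=cut[removed.to_numpy()])
    return table.loc[~removed].reset_index(drop=True), log


def filter_poor_segmentation(
    table: pd.DataFrame,
    masks: LabelMasks | None = None,
    min_area: float = 20.0,
    max_area: float | None = None,
    min_solidity: float = 0.8,
    flag_brighter_neighbor: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cells outside area bounds or below the solidity bound.

    Cells whose mask touches a brighter neighbor's dilated mask are flagged
    (``touches_brighter_neighbor`` appended to ``qc_flags``) but not
    removed, for optional exclusion.  Solidity and neighbor checks need
    ``masks``; with table-only input the area rule alone applies.
    """
    area = table["area"].to_numpy(dtype=float)
    removed = area < min_area
    reason = np.where(removed, "below_min_area", "")
    if max_area is not None:
        too_big = area > max_area
        reason = np.where(too_big & ~removed, "above_max_area", reason)
        removed |= too_big

    table = table.copy()
    if masks is not None and "label" in table.columns:
        sol = mask_solidity(masks.cell)
        sol_vals = table["label"].map(sol).to_numpy(dtype=float)
        low_sol = np.nan_to_num(sol_vals, nan=1.0) < min_solidity
        reason = np.where(low_sol & ~removed, "low_solidity", reason)
        removed |= low_sol
        if flag_brighter_neighbor:
            flagged = _brighter_neighbor_labels(table, masks)
            hit = table["label"].isin(flagged).to_numpy()
            table.loc[hit, "qc_flags"] = table.loc[hit, "qc_flags"].apply(
                lambda s: s if "touches_brighter_neighbor" in s
                else (s + ";" if s else "") + "touches_brighter_neighbor"
            )
    removed_s = pd.Series(removed, index=table.index)
    log = pd.DataFrame(
        {"cell_id": table.loc[removed_s, "cell_id"], "reason": reason[removed]}
    ).reset_index(drop=True)
    return table.loc[~removed_s].reset_index(drop=True), log


def _brighter_neighbor_labels(table: pd.DataFrame, masks: LabelMasks) -> set:
    """Labels of cells touching (within 1 px of) a brighter neighbor.

    Brightness reference: mean over all whole-cell marker means, so a dim
    cell bordering a strongly stained one is flagged as at risk of
    spillover."""
    cell = masks.cell
    marker_cols = [c for c in table.columns if c.endswith("_whole_cell")]
    bright = table.set_index("label")[marker_cols].mean(axis=1)
    dil = ndi.grey_dilation(cell, size=(3, 3))
    ero = ndi.grey_erosion(np.where(cell == 0, np.iinfo(np.int32).max, cell), size=(3, 3))
    flagged: set = set()
    # boundary pixels where two different labels meet after 1-px dilation
    touch = (dil != cell) & (cell > 0) & (dil > 0)
    pairs = set(zip(cell[touch].tolist(), dil[touch].tolist()))
    touch2 = (ero != cell) & (cell > 0) & (ero != np.iinfo(np.int32).max) & (ero > 0)
    pairs |= set(zip(cell[touch2].tolist(), ero[touch2].tolist()))
    for a, b in pairs:
        if a == b or a not in bright.index or b not in bright.index:
            continue
        if bright[b] > bright[a]:
            flagged.add(a)
    return flagged


def run_qc(
    table: pd.DataFrame,
    masks: LabelMasks | None = None,
    exclusion: np.ndarray | None = None,
    autofluorescence_quantile: float = 0.99,
    autofluorescence_cutoff: float | None = None,
    min_area: float = 20.0,
    max_area: float | None = None,
    min_solidity: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules in study order; returns (table, full log)."""
    logs = []
    if exclusion is not None:
        table, log = apply_exclusion_mask(table, exclusion)
        logs.append(log)
    table, log = filter_autofluorescence(
        table, quantile=autofluorescence_quantile, cutoff=autofluorescence_cutoff
    )
    logs.append(log)
    table, log = filter_poor_segmentation(
        table, masks, min_area=min_area, max_area=max_area, min_solidity=min_solidity
    )
    logs.append(log)
    full_log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    return table, full_log
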