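"""Nucleus / whole-cell / cytoplasm segmentation.

A classical threshold-watershed-expansion segmenter producing the three
aligned label masks the rest of the pipeline consumes: nuclei from the DAPI
channel (Otsu threshold, distance-transform watershed to split touching
nuclei, size filter), whole cells by seeded expansion from each nucleus
(bounded by a membrane-marker footprint when one is supplied, by a fixed
radius otherwise), and cytoplasm as the per-label set difference
cell minus nucleus.  The output contract — three label images sharing one
consecutive label set — is segmenter-agnostic, so externally produced masks
(e.g. from a deep-learning segmenter) can be imported through the same
:class:`LabelMasks` container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, relabel_sequential, watershed

from .errors import ConsistencyError, DimensionError


@dataclass
class SegmentationParams:
    """Tunables of the classical segmenter.

    ``min_area``/``max_area`` bound accepted nucleus sizes in px^2;
    ``distance_smooth_sigma`` smooths the distance transform before
    watershed seeding; ``peak_min_distance`` is the minimum separation of
    watershed seeds; ``max_expansion`` caps whole-cell growth from the
    nucleus boundary in px.
    """

    threshold: float | None = None  # None -> Otsu
    min_area: int = 20
    max_area: int | None = None
    distance_smooth_sigma: float = 1.0
    peak_min_distance: int = 3
    max_expansion: int = 6


@dataclass
class LabelMasks:
    """Aligned nucleus / cell / cytoplasm integer label images."""

    nucleus: np.ndarray
    cell: np.ndarray
    cytoplasm: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.nucleus.max())

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.nucleus[self.nucleus > 0])

    def validate(self) -> None:
        if not (self.nucleus.shape == self.cell.shape == self.cytoplasm.shape):
            raise DimensionError("mask shapes disagree")
        nuc_labels = set(np.unique(self.nucleus)) - {0}
        cell_labels = set(np.unique(self.cell)) - {0}
        if nuc_labels != cell_labels:
            raise ConsistencyError("nucleus and cell label sets differ")
        inside = self.cell[self.nucleus > 0]
        if not np.array_equal(inside, self.nucleus[self.nucleus > 0]):
            raise ConsistencyError("some nucleus pixels lie outside their cell region")
        expected_cyto = np.where(self.nucleus > 0, 0, self.cell)
        if not np.array_equal(self.cytoplasm, expected_cyto):
            raise ConsistencyError("cytoplasm is not cell minus nucleus")

    def empty_cytoplasm_labels(self) -> np.ndarray:
        """Labels whose nucleus fills the whole cell (no cytoplasm pixels)."""
        present = set(np.unique(self.cytoplasm)) - {0}
        return np.array(sorted(set(self.labels.tolist()) - present), dtype=int)

    def write(self, prefix) -> None:
        tifffile.imwrite(f"{prefix}_nucleus.tif", self.nucleus.astype(np.int32))
        tifffile.imwrite(f"{prefix}_cell.tif", self.cell.astype(np.int32))
        tifffile.imwrite(f"{prefix}_cytoplasm.tif", self.cytoplasm.astype(np.int32))

    @classmethod
    def read(cls, prefix) -> "LabelMasks":
        masks = cls(
            nucleus=tifffile.imread(f"{prefix}_nucleus.tif"),
            cell=tifffile.imread(f"{prefix}_cell.tif"),
            cytoplasm=tifffile.imread(f"{prefix}_cytoplasm.tif"),
        )
        masks.validate()
        return masks


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Label nuclei in a DAPI image.

    Otsu (or fixed) threshold -> distance-transform watershed to split
    touching nuclei -> size filter -> consecutive relabeling.  An image with
    empty foreground yields zero labels with a warning, not an error.
    """
    params = params or SegmentationParams()
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise DimensionError("segment_nuclei expects a 2-D single-channel image")
    if dapi.max() == dapi.min():
        warnings.warn("constant DAPI image: no nuclei found", stacklevel=2)
        return np.zeros(dapi.shape, dtype=np.int32)
    thr = params.threshold if params.threshold is not None else threshold_otsu(dapi)
    fg = dapi > thr
    if not fg.any():
        warnings.warn("empty foreground after threshold: no nuclei found", stacklevel=2)
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(fg)
    smoothed = ndi.gaussian_filter(distance, params.distance_smooth_sigma)
    peaks = peak_local_max(
        smoothed, min_distance=params.peak_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers, mask=fg)

    areas = np.bincount(labels.ravel())
    bad = np.zeros(len(areas), dtype=bool)
    bad[1:] = areas[1:] < params.min_area
    if params.max_area is not None:
        bad[1:] |= areas[1:] > params.max_area
    labels[bad[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    nucleus_labels: np.ndarray,
    membrane: np.ndarray | None = None,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Grow whole-cell regions from nucleus seeds.

    Without a membrane channel, each nucleus expands isotropically by up to
    ``max_expansion`` px (nearest-seed tie-break, regions never overlap).
    With a membrane channel, expansion is additionally confined to the
    membrane-positive footprint (Otsu threshold), so cells stop at the edge
    of their stained body.  Nucleus pixels always keep their label, so
    nucleus <= cell per label.
    """
    params = params or SegmentationParams()
    nucleus_labels = np.asarray(nucleus_labels)
    if membrane is None:
        cells = expand_labels(nucleus_labels, distance=params.max_expansion)
    else:
        membrane = np.asarray(membrane, dtype=float)
        if membrane.shape != nucleus_labels.shape:
            raise DimensionError("membrane image and nucleus mask shapes differ")
        if membrane.max() > membrane.min():
            fg = membrane > threshold_otsu(membrane)
        else:
            fg = np.zeros(membrane.shape, dtype=bool)
        fg |= nucleus_labels > 0
        reach = ndi.distance_transform_edt(nucleus_labels == 0) <= params.max_expansion
        mask = fg & reach
        distance = ndi.distance_transform_edt(nucleus_labels == 0)
        cells = watershed(distance, markers=nucleus_labels, mask=mask)
        # guarantee nucleus pixels keep their own label
        nz = nucleus_labels > 0
        cells[nz] = nucleus_labels[nz]
    return cells.astype(np.int32)


def derive_cytoplasm(nucleus_labels: np.ndarray, cell_labels: np.ndarray) -> np.ndarray:
    """Cytoplasm = cell minus nucleus, per label.

    A cell whose nucleus fills it has an empty cytoplasm; that is flagged
    with a warning, not an error."""
    nucleus_labels = np.asarray(nucleus_labels)
    cell_labels = np.asarray(cell_labels)
    if nucleus_labels.shape != cell_labels.shape:
        raise DimensionError("mask shapes differ")
    nuc_set = set(np.unique(nucleus_labels)) - {0}
    cell_set = set(np.unique(cell_labels)) - {0}
    if nuc_set != cell_set:
        raise ConsistencyError(f"label sets differ: {sorted(nuc_set ^ cell_set)}")
    cyto = np.where(nucleus_labels > 0, 0, cell_labels).astype(np.int32)
    empty = nuc_set - (set(np.unique(cyto)) - {0})
    if empty:
        warnings.warn(f"{len(empty)} cells have empty cytoplasm", stacklevel=2)
    return cyto


def segment(
    dapi: np.ndarray,
    membrane: np.ndarray | None = None,
    params: SegmentationParams | None = None,
) -> LabelMasks:
    """Full nucleus -> cell -> cytoplasm segmentation of one field."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(dapi, params)
    cells = segment_cells(nuclei, membrane, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cyto = derive_cytoplasm(nuclei, cells)
    masks = LabelMasks(nucleus=nuclei, cell=cells, cytoplasm=cyto)
    masks.validate()
    return masks


def mask_solidity(labels: np.ndarray) -> dict:
    """Per-label solidity (area / convex area), for poor-segmentation QC."""
    return {p.label: float(p.solidity) for p in regionprops(np.asarray(labels))}
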