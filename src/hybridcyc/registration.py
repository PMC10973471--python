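"""Rigid alignment of cyclic staining rounds on the nuclear channel.

Successive staining rounds of one specimen drift by a small rigid
translation on the stage.  The drift between a moving round and the
reference round is recovered by phase correlation on the DAPI channel with
subpixel (upsampled cross-correlation) refinement, and the single recovered
transform is applied identically to every channel of that round.  Rotation
is out of scope: slide-scan drift is translational.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .errors import DegenerateImageError, DimensionError, LayoutError
from .layout import RoundLayout, default_layout

DEFAULT_UPSAMPLE = 50


@dataclass
class RigidTransform:
    """Translation (dy, dx) of a moving round relative to the reference.

    Positive ``dy``/``dx`` means the moving image content sits ``dy`` rows
    down and ``dx`` columns right of the reference; :func:`apply_transform`
    shifts by the negation to align it back.
    """

    dy: float
    dx: float
    round_id: int | None = None

    def inverse(self) -> "RigidTransform":
        return RigidTransform(-self.dy, -self.dx, self.round_id)


def estimate_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample_factor: int = DEFAULT_UPSAMPLE,
) -> RigidTransform:
    """Estimate the rigid drift of ``moving`` relative to ``reference``.

    Phase correlation with upsampled subpixel refinement; residual error on
    synthetic integer shifts is well below half a pixel.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise DimensionError(f"shape mismatch: {reference.shape} vs {moving.shape}")
    if reference.std() == 0 or moving.std() == 0:
        raise DegenerateImageError("cannot register a constant image")
    correction, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    # phase_cross_correlation returns the shift that registers `moving`
    # onto `reference`; the drift itself is its negation.
    return RigidTransform(dy=float(-correction[0]), dx=float(-correction[1]))


def apply_transform(image: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample ``image`` so its content aligns with the reference frame.

    Out-of-frame pixels are filled with 0 (and should be excluded from
    downstream masks)."""
    if transform.dy == 0 and transform.dx == 0:
        return np.asarray(image, dtype=float).copy()
    return ndi.shift(
        np.asarray(image, dtype=float),
        (-transform.dy, -transform.dx),
        order=order,
        cval=0.0,
        prefilter=False,
    )


def register_rounds(
    stacks: dict,
    channels: dict,
    layout: RoundLayout | None = None,
    reference_round: int = 1,
    upsample_factor: int = DEFAULT_UPSAMPLE,
) -> tuple[dict, list[RigidTransform]]:
    """Align every round's stack to the reference round via its DAPI channel.

    Returns the aligned stacks (float arrays, same keys/shapes) and the list
    of per-round transforms.  The reference round's transform is identically
    (0, 0)."""
    layout = layout or default_layout()
    if reference_round not in stacks:
        raise LayoutError(f"reference round {reference_round} not in stacks")

    def dapi_of(r: int) -> np.ndarray:
        chans = channels[r]
        if layout.nuclear_channel not in chans:
            raise LayoutError(f"round {r} has no {layout.nuclear_channel} channel")
        return np.asarray(stacks[r][chans.index(layout.nuclear_channel)], dtype=float)

    ref = dapi_of(reference_round)
    aligned: dict = {}
    transforms: list[RigidTransform] = []
    for r in sorted(stacks):
        if r == reference_round:
            t = RigidTransform(0.0, 0.0, round_id=r)
            aligned[r] = np.asarray(stacks[r], dtype=float).copy()
        else:
            t = estimate_translation(ref, dapi_of(r), upsample_factor)
            t.round_id = r
            aligned[r] = np.stack([apply_transform(c, t) for c in stacks[r]])
        transforms.append(t)
    return aligned, transforms


def write_transform_log(path, transforms: list[RigidTransform]) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(t) for t in transforms], fh, indent=2)


def read_transform_log(path) -> list[RigidTransform]:
    with open(path) as fh:
        return [RigidTransform(**d) for d in json.load(fh)]
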