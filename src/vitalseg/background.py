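"""Fluorescence background estimation and subtraction.

Background is sampled from the inter-organoid space of no-treatment control
wells only: the mask is slightly dilated (disk, radius 2 px) so pixels that
hug organoid boundaries do not leak signal into the sample, and the *median*
intensity outside the dilated mask is taken per image and channel.  The
median is deliberate — detached single cells and debris dot the background
with bright fluorescent loci, and a mean would overcorrect.  Per-image
medians are averaged across control images and the resulting per-channel
scalars are subtracted from every image in the experiment, controls and
treated wells alike, clipping at zero (negative intensity is non-physical
and would corrupt the viability ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .io import ImageSet
from .segmentation import LabelMap


@dataclass
class BackgroundEstimate:
    live_background: float  # a.u.
    dead_background: float  # a.u.
    n_images: int

    def __post_init__(self) -> None:
        if self.live_background < 0 or self.dead_background < 0:
            raise ValueError("background estimates must be >= 0")
        if self.n_images < 1:
            raise ValueError("background estimate requires >= 1 control image")


def dilate_mask(label_map: LabelMap, radius: int = 2) -> np.ndarray:
    """Dilate the foreground with a discrete disk: (i, j) in the element
    iff i² + j² ≤ r².  Radius 0 is the identity."""
    if radius < 0 or int(radius) != radius:
        raise ValueError(f"radius must be a non-negative integer, got {radius}")
    fg = label_map.foreground
    if radius == 0:
        return fg.copy()
    return ndi.binary_dilation(fg, structure=disk(int(radius)))


def estimate_background(
    control_sets: Sequence[tuple[ImageSet, LabelMap]], radius: int = 2
) -> BackgroundEstimate:
    """Median background per image/channel, averaged over control images.

    Only no-treatment images should be supplied; each must retain at least
    1% of its pixels outside the dilated mask, otherwise there is no
    background sample to take the median over.
    """
    if not control_sets:
        raise ValueError("estimate_background requires >= 1 control image")
    live_medians, dead_medians = [], []
    for image_set, label_map in control_sets:
        outside = ~dilate_mask(label_map, radius)
        if outside.mean() < 0.01:
            raise ValueError(
                f"dilated mask covers >= 99% of image {image_set.well_id}: "
                "no background sample"
            )
        live_medians.append(float(np.median(image_set.live[outside])))
        dead_medians.append(float(np.median(image_set.dead[outside])))
    return BackgroundEstimate(
        live_background=float(np.mean(live_medians)),
        dead_background=float(np.mean(dead_medians)),
        n_images=len(control_sets),
    )


def subtract_background(image_set: ImageSet, bg: BackgroundEstimate) -> ImageSet:
    """Subtract the per-channel background, clipping at 0; brightfield is
    untouched and all metadata is preserved."""
    if not (np.isfinite(bg.live_background) and np.isfinite(bg.dead_background)):
        raise ValueError("background estimate must be finite")
    return image_set.with_channels(
        live=np.clip(image_set.live - bg.live_background, 0.0, None),
        dead=np.clip(image_set.dead - bg.dead_background, 0.0, None),
    )
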