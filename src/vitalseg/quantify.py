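"""Nodule-by-nodule readouts: area, intensity, viability, live/dead area.

Per indexed organoid the pipeline reports

* total area           = pixel count × pixel area (µm²)
* viability            = I_live / (I_live + I_dead), the mean calcein-AM
                         intensity against the mean PI intensity over the
                         object's pixels; 1 is fully live, 0 fully dead
* live (dead) area     = area of object pixels whose live (dead) intensity
                         exceeds a fixed experiment-wide threshold
* fractional live area = live area / total area

The live threshold is Otsu's method applied to the pooled within-mask
live-channel pixels of the no-treatment controls, scaled by a factor
(default 0.4) that sets the dynamic range between the total-killing (no
live area) and no-treatment (all live area) anchors.  The dead threshold
is calibrated symmetrically on the total-killing controls' dead channel.

Viability is scale-invariant to using sums instead of means, because both
channels integrate over the same pixel set; means are reported so
``mean_live``/``mean_dead`` do not grow with object size.  An object with
zero intensity in both channels has undefined viability and is reported
with a missing value rather than dropped, so the area statistics stay
complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageSet
from .segmentation import LabelMap, otsu_threshold

#: Column order of the per-object table; see docs for units.
RECORD_COLUMNS = [
    "object_id",
    "area_px",
    "total_area",
    "mean_live",
    "mean_dead",
    "viability",
    "live_area",
    "frac_live_area",
    "dead_area",
    "frac_dead_area",
    "centroid_row",
    "centroid_col",
]


@dataclass
class LiveThreshold:
    """Fixed experiment-wide intensity threshold (a.u.)."""

    raw_otsu: float
    factor: float = 0.4
    value: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("threshold factor must be > 0")
        expected = self.raw_otsu * self.factor
        if self.value is None:
            self.value = expected
        elif not np.isclose(self.value, expected):
            raise ValueError("value must equal raw_otsu * factor")


def object_intensities(label_map: LabelMap, channel: np.ndarray) -> np.ndarray:
    """Mean channel intensity per object, aligned with object_ids."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != label_map.labels.shape:
        raise ValueError("channel shape must match the label map")
    if label_map.n_objects == 0:
        return np.zeros(0)
    return np.asarray(
        ndi.mean(channel, labels=label_map.labels, index=label_map.object_ids)
    )


def viability(mean_live, mean_dead):
    """Live-fraction intensity ratio live / (live + dead) in [0, 1].

    Works element-wise on arrays.  Where both intensities are zero the
    ratio is undefined and NaN is returned (flagged missing, not an error).
    """
    live = np.asarray(mean_live, dtype=np.float64)
    dead = np.asarray(mean_dead, dtype=np.float64)
    if np.any(live < 0) or np.any(dead < 0):
        raise ValueError("intensities must be >= 0 (background-clipped)")
    total = live + dead
    out = np.full(np.broadcast(live, dead).shape, np.nan)
    np.divide(live, total, out=out, where=total > 0)
    return float(out) if out.ndim == 0 else out


def _pooled_masked_pixels(
    control_sets: Sequence[tuple[ImageSet, LabelMap]], channel: str
) -> np.ndarray:
    chunks = [
        getattr(image_set, channel)[label_map.foreground]
        for image_set, label_map in control_sets
    ]
    pooled = np.concatenate(chunks) if chunks else np.zeros(0)
    if pooled.size < 2:
        raise ValueError("no within-mask pixels to calibrate a threshold on")
    return pooled


def calibrate_live_threshold(
    control_sets: Sequence[tuple[ImageSet, LabelMap]],
    factor: float = 0.4,
    bins: int = 256,
) -> LiveThreshold:
    """Otsu over pooled within-mask live pixels of no-treatment images,
    scaled by ``factor``; one fixed value for the whole experiment."""
    if not control_sets:
        raise ValueError("live-threshold calibration requires >= 1 control image")
    raw = otsu_threshold(_pooled_masked_pixels(control_sets, "live"), bins)
    return LiveThreshold(raw_otsu=raw, factor=factor)


def calibrate_dead_threshold(
    control_sets: Sequence[tuple[ImageSet, LabelMap]],
    factor: float = 0.4,
    bins: int = 256,
) -> LiveThreshold:
    """Dead-channel analog, calibrated on total-killing controls."""
    if not control_sets:
        raise ValueError("dead-threshold calibration requires >= 1 control image")
    raw = otsu_threshold(_pooled_masked_pixels(control_sets, "dead"), bins)
    return LiveThreshold(raw_otsu=raw, factor=factor)


def _thresholded_area(
    label_map: LabelMap, channel: np.ndarray, threshold: LiveThreshold
) -> tuple[np.ndarray, np.ndarray]:
    """Per-object (area µm², fraction of total area) above the threshold.

    Strict inequality: a pixel counts iff its intensity exceeds the value.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != label_map.labels.shape:
        raise ValueError("channel shape must match the label map")
    if label_map.n_objects == 0:
        return np.zeros(0), np.zeros(0)
    above = (channel > threshold.value).astype(np.float64)
    counts = np.asarray(
        ndi.sum_labels(above, labels=label_map.labels, index=label_map.object_ids)
    )
    return counts * label_map.pixel_area, counts / label_map.areas_px()


def object_live_area(label_map, live, threshold):
    return _thresholded_area(label_map, live, threshold)


def object_dead_area(label_map, dead, threshold):
    return _thresholded_area(label_map, dead, threshold)


def quantify_image_set(
    image_set: ImageSet,
    label_map: LabelMap,
    live_threshold: LiveThreshold,
    dead_threshold: LiveThreshold | None = None,
) -> pd.DataFrame:
    """Per-object table for one image (one row per indexed organoid).

    Fluorescence channels must already be background-subtracted and the
    label map must be the final (post-focus-filter) mask.
    """
    ids = label_map.object_ids
    df = pd.DataFrame(index=range(len(ids)), columns=RECORD_COLUMNS, dtype=float)
    df["object_id"] = ids
    if ids:
        areas_px = label_map.areas_px()
        mean_live = object_intensities(label_map, image_set.live)
        mean_dead = object_intensities(label_map, image_set.dead)
        live_area, frac_live = object_live_area(label_map, image_set.live, live_threshold)
        centroids = np.asarray(
            ndi.center_of_mass(label_map.foreground, label_map.labels, ids)
        )
        df["area_px"] = areas_px
        df["total_area"] = areas_px * label_map.pixel_area
        df["mean_live"] = mean_live
        df["mean_dead"] = mean_dead
        df["viability"] = viability(mean_live, mean_dead)
        df["live_area"] = live_area
        df["frac_live_area"] = frac_live
        if dead_threshold is not None:
            dead_area, frac_dead = object_dead_area(
                label_map, image_set.dead, dead_threshold
            )
            df["dead_area"] = dead_area
            df["frac_dead_area"] = frac_dead
        df["centroid_row"] = centroids[:, 0]
        df["centroid_col"] = centroids[:, 1]
    meta = {
        "well_id": image_set.well_id,
        "group": image_set.group,
        "dose": np.nan if image_set.dose is None else image_set.dose,
        "dose_unit": image_set.dose_unit,
    }
    for i, (k, v) in enumerate(meta.items()):
        df.insert(i, k, v)
    df["object_id"] = df["object_id"].astype(int)
    return df


def normalize_viability(
    records: pd.DataFrame, control_records: pd.DataFrame
) -> pd.DataFrame:
    """Add ``normalized_viability`` = viability / median control viability.

    Missing viabilities stay missing; the scaling is monotone so within-
    group ordering is preserved.
    """
    controls = control_records["viability"].dropna()
    if controls.empty:
        raise ValueError("control records contain no defined viability")
    med = float(controls.median())
    if med == 0:
        raise ValueError("control median viability is 0; cannot normalize")
    out = records.copy()
    out["normalized_viability"] = out["viability"] / med
    return out
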