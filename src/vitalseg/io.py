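"""Image and manifest I/O.

Each well (or field) is described by a triplet of single-plane grayscale
rasters — transmitted-light brightfield, calcein-AM ("live") fluorescence
and propidium-iodide ("dead") fluorescence — plus pixel-scale metadata and
the experimental group the well belongs to.  A plate manifest (CSV or JSON)
binds file paths to wells, groups and doses.

Pixel scale is deliberately a *required* manifest field: the physical
area per pixel depends on the optics and must be stated explicitly, since
every area readout downstream is reported in µm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

#: Allowed experimental groups.  ``no_treatment`` and ``total_killing``
#: anchor the viability dynamic range; everything else is ``treatment``.
GROUPS = ("no_treatment", "total_killing", "treatment")

#: Channel order assumed when a single multi-channel TIFF is supplied.
DEFAULT_CHANNEL_ORDER = ("brightfield", "live", "dead")


class ManifestError(ValueError):
    """Raised when a plate manifest is malformed or incomplete."""


@dataclass
class ImageSet:
    """One well/field: registered brightfield + live + dead rasters.

    Intensities are carried as float64 in the acquisition's native scale
    (arbitrary units); integer bit depths are widened without rescaling so
    relative intensities within one experiment are preserved.
    """

    brightfield: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    pixel_area: float  # µm² per pixel
    well_id: str
    group: str
    dose: float | None = None
    dose_unit: str | None = None

    def __post_init__(self) -> None:
        self.brightfield = _as_raster(self.brightfield, "brightfield")
        self.live = _as_raster(self.live, "live")
        self.dead = _as_raster(self.dead, "dead")
        if not (self.brightfield.shape == self.live.shape == self.dead.shape):
            raise ValueError(
                "channel shape mismatch: brightfield "
                f"{self.brightfield.shape}, live {self.live.shape}, "
                f"dead {self.dead.shape}"
            )
        if not self.pixel_area > 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape

    def with_channels(
        self,
        brightfield: np.ndarray | None = None,
        live: np.ndarray | None = None,
        dead: np.ndarray | None = None,
    ) -> "ImageSet":
        """Copy with some channels replaced; metadata is carried unchanged."""
        return replace(
            self,
            brightfield=self.brightfield if brightfield is None else brightfield,
            live=self.live if live is None else live,
            dead=self.dead if dead is None else dead,
        )


def _as_raster(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} raster must be 2D, got shape {arr.shape}")
    arr = arr.astype(np.float64, copy=False)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} raster contains non-finite values")
    if arr.min() < 0:
        raise ValueError(f"{name} raster contains negative intensities")
    return arr


@dataclass
class ManifestEntry:
    well_id: str
    group: str
    path_brightfield: Path
    path_live: Path
    path_dead: Path
    dose: float | None = None
    dose_unit: str | None = None
    tile: int | None = None  # 0..3 when the well is a 2x2 mosaic


@dataclass
class PlateManifest:
    entries: list[ManifestEntry]
    pixel_area: float
    experiment_id: str = "experiment"

    def groups(self) -> set[str]:
        return {e.group for e in self.entries}

    def validate(self, require_controls: bool = True) -> None:
        """Check files exist and, for a full run, both controls are present."""
        if not self.entries:
            raise ManifestError("manifest has no entries")
        if not self.pixel_area > 0:
            raise ManifestError("manifest pixel_area must be > 0")
        for e in self.entries:
            if e.group not in GROUPS:
                raise ManifestError(f"unknown group {e.group!r} for well {e.well_id}")
            for p in (e.path_brightfield, e.path_live, e.path_dead):
                if not Path(p).is_file():
                    raise ManifestError(f"missing image file: {p}")
        if require_controls:
            missing = {"no_treatment", "total_killing"} - self.groups()
            if missing:
                raise ManifestError(
                    "all experiments require no treatment and total killing "
                    f"control groups; manifest lacks: {sorted(missing)}"
                )


def read_manifest(path: str | Path) -> PlateManifest:
    """Read a plate manifest from CSV or JSON.

    CSV columns: well_id, group, dose, dose_unit, path_brightfield,
    path_live, path_dead, pixel_area (constant per plate) and optionally
    tile.  JSON uses the same keys, with ``pixel_area``/``experiment_id``
    at the top level and rows under ``entries``.  Relative image paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload["entries"]
        pixel_area = float(payload["pixel_area"])
        experiment_id = str(payload.get("experiment_id", path.stem))
    else:
        df = pd.read_csv(path)
        if "pixel_area" not in df.columns:
            raise ManifestError("CSV manifest requires a pixel_area column")
        pixel_area = float(df["pixel_area"].iloc[0])
        if not np.allclose(df["pixel_area"], pixel_area):
            raise ManifestError("pixel_area must be constant within one manifest")
        experiment_id = str(df["experiment_id"].iloc[0]) if "experiment_id" in df else path.stem
        rows = df.to_dict("records")

    entries = []
    for row in rows:
        dose = row.get("dose")
        dose = None if dose is None or (isinstance(dose, float) and np.isnan(dose)) else float(dose)
        tile = row.get("tile")
        tile = None if tile is None or (isinstance(tile, float) and np.isnan(tile)) else int(tile)
        dose_unit = row.get("dose_unit")
        if isinstance(dose_unit, float) and np.isnan(dose_unit):
            dose_unit = None
        entries.append(
            ManifestEntry(
                well_id=str(row["well_id"]),
                group=str(row["group"]),
                dose=dose,
                dose_unit=dose_unit,
                path_brightfield=base / str(row["path_brightfield"]),
                path_live=base / str(row["path_live"]),
                path_dead=base / str(row["path_dead"]),
                tile=tile,
            )
        )
    return PlateManifest(entries=entries, pixel_area=pixel_area, experiment_id=experiment_id)


def _read_plane(path: Path) -> np.ndarray:
    if not Path(path).is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(str(path))
    return np.asarray(arr)


def load_image_set(
    entry: ManifestEntry,
    pixel_area: float,
    channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
) -> ImageSet:
    """Load one manifest entry into an :class:`ImageSet`.

    The three channel paths may point at three single-plane grayscale TIFFs,
    or all at one multi-channel TIFF whose planes follow ``channel_order``.
    """
    paths = {
        "brightfield": Path(entry.path_brightfield),
        "live": Path(entry.path_live),
        "dead": Path(entry.path_dead),
    }
    channels: dict[str, np.ndarray] = {}
    if len({str(p) for p in paths.values()}) == 1:
        stack = _read_plane(paths["brightfield"])
        if stack.ndim != 3 or stack.shape[0] < 3:
            raise ValueError(
                f"multi-channel TIFF must have >= 3 planes, got shape {stack.shape}"
            )
        for i, name in enumerate(channel_order):
            channels[name] = stack[i]
    else:
        for name, p in paths.items():
            channels[name] = _read_plane(p)
    return ImageSet(
        brightfield=channels["brightfield"],
        live=channels["live"],
        dead=channels["dead"],
        pixel_area=pixel_area,
        well_id=entry.well_id,
        group=entry.group,
        dose=entry.dose,
        dose_unit=entry.dose_unit,
    )


def tile_mosaic(image_sets: Sequence[ImageSet]) -> ImageSet:
    """Assemble four equally-sized tiles into one seamless 2×2 mosaic.

    Tile order is row-major: top-left, top-right, bottom-left, bottom-right.
    Organoids spanning tile seams merge into single objects downstream,
    which is the point of analysing the mosaic rather than the tiles.
    """
    if len(image_sets) != 4:
        raise ValueError(f"a mosaic requires exactly 4 tiles, got {len(image_sets)}")
    first = image_sets[0]
    for t in image_sets[1:]:
        if t.shape != first.shape:
            raise ValueError("all mosaic tiles must share one shape")
        if t.pixel_area != first.pixel_area:
            raise ValueError("all mosaic tiles must share one pixel_area")
        if t.well_id != first.well_id:
            raise ValueError("mosaic tiles must come from one well")

    def block(channel: str) -> np.ndarray:
        a, b, c, d = (getattr(t, channel) for t in image_sets)
        return np.block([[a, b], [c, d]])

    return ImageSet(
        brightfield=block("brightfield"),
        live=block("live"),
        dead=block("dead"),
        pixel_area=first.pixel_area,
        well_id=first.well_id,
        group=first.group,
        dose=first.dose,
        dose_unit=first.dose_unit,
    )


def write_image_set(image_set: ImageSet, dir_path: str | Path, dtype=np.uint16) -> dict[str, Path]:
    """Write the three channels as single-plane TIFFs; returns the paths.

    Integer dtypes round to the nearest level and clip at the dtype range,
    which round-trips exactly for rasters that are already integral.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name in ("brightfield", "live", "dead"):
        arr = getattr(image_set, name)
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            arr = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
        else:
            arr = arr.astype(dtype)
        p = dir_path / f"{image_set.well_id}_{name}.tif"
        tifffile.imwrite(str(p), arr)
        out[name] = p
    return out
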