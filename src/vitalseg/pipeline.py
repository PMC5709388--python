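"""End-to-end analysis run: manifest in, per-object tables and report out.

Canonical stage order:

1. load images (assembling 2×2 mosaics where the manifest marks tiles);
2. segment the control wells (brightfield mask + focus filter on raw
   fluorescence) to obtain masks for background sampling;
3. estimate the per-channel background from the no-treatment controls and
   subtract it experiment-wide;
4. re-segment every well, the focus filter now using corrected channels —
   these label maps are the definitive object indices;
5. calibrate the live threshold on no-treatment controls and the dead
   threshold on total-killing controls;
6. quantify every object, normalize viability to the no-treatment median;
7. summarize per group/dose, fit a dose-response curve when enough dose
   levels exist, and render viability heatmaps and live-area maps.

Brightfield masking deliberately precedes background subtraction (it uses
only the brightfield channel); every parameter that shaped a run is echoed
into the JSON report so the run is reconstructible from report + inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    dose_response_fit,
    render_live_area_map,
    render_viability_heatmap,
    summarize_group,
)
from .background import estimate_background, subtract_background
from .io import ImageSet, PlateManifest, load_image_set, read_manifest, tile_mosaic
from .quantify import (
    calibrate_dead_threshold,
    calibrate_live_threshold,
    normalize_viability,
    quantify_image_set,
)
from .segmentation import SegmentationParams, segment_image_set

logger = logging.getLogger("vitalseg")


@dataclass
class RunConfig:
    """Experiment-level configuration; defaults are the pipeline's
    reference parameters (sensitivity 0.55, 65 px neighborhood, 1950 µm²
    size cut, threshold factor 0.4, 2 px background dilation)."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    background_radius: int = 2
    live_threshold_factor: float = 0.4
    dead_threshold_factor: float = 0.4
    normalize: bool = True
    dose_response_model: str = "exponential_decay"
    render_maps: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys raise."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text) or {}
        else:
            payload = json.loads(text)
        seg = payload.pop("segmentation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        seg_known = {f.name for f in dataclasses.fields(SegmentationParams)}
        unknown = set(seg) - seg_known
        if unknown:
            raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
        return cls(segmentation=SegmentationParams(**seg), **payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    records: pd.DataFrame
    summaries: list
    background: "BackgroundEstimate"
    live_threshold: "LiveThreshold"
    dead_threshold: "LiveThreshold | None"
    dose_response: "DoseResponseFit | None"
    report: dict
    label_maps: dict


def _load_wells(manifest: PlateManifest) -> list[ImageSet]:
    """Load every well, assembling 2×2 mosaics where tiles are marked."""
    tiled: dict[str, list] = {}
    wells: list[ImageSet] = []
    for entry in manifest.entries:
        if entry.tile is None:
            wells.append(load_image_set(entry, manifest.pixel_area))
        else:
            tiled.setdefault(entry.well_id, []).append(entry)
    for well_id, entries in tiled.items():
        entries.sort(key=lambda e: e.tile)
        if [e.tile for e in entries] != [0, 1, 2, 3]:
            raise ValueError(f"well {well_id}: mosaic requires tiles 0..3")
        wells.append(
            tile_mosaic([load_image_set(e, manifest.pixel_area) for e in entries])
        )
    return wells


def run_analyze(
    manifest: PlateManifest | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full analysis; optionally write all artifacts to disk."""
    config = config or RunConfig()
    logging.basicConfig(level=config.log_level)
    if not isinstance(manifest, PlateManifest):
        manifest = read_manifest(manifest)
    manifest.validate(require_controls=True)
    params = config.segmentation

    wells = _load_wells(manifest)
    logger.info("loaded %d wells", len(wells))

    # control masks on raw images, for background sampling only
    nt_wells = [w for w in wells if w.group == "no_treatment"]
    control_maps = [(w, segment_image_set(w, params)) for w in nt_wells]
    background = estimate_background(control_maps, radius=config.background_radius)
    logger.info(
        "background: live %.2f, dead %.2f over %d control images",
        background.live_background,
        background.dead_background,
        background.n_images,
    )

    corrected = [subtract_background(w, background) for w in wells]

    # definitive segmentation: focus filter sees corrected fluorescence
    label_maps = {}
    counts = {}
    for w in corrected:
        from .segmentation import adaptive_binarize, focus_filter, label_and_size_filter

        binary = adaptive_binarize(w.brightfield, params)
        pre = label_and_size_filter(binary, params, w.pixel_area)
        final = focus_filter(pre, w.live, w.dead, params)
        label_maps[w.well_id] = final
        counts[w.well_id] = {
            "post_size_filter": pre.n_objects,
            "post_focus_filter": final.n_objects,
        }
        logger.info(
            "well %s: %d objects after size filter, %d after focus filter",
            w.well_id,
            pre.n_objects,
            final.n_objects,
        )

    nt = [(w, label_maps[w.well_id]) for w in corrected if w.group == "no_treatment"]
    tk = [(w, label_maps[w.well_id]) for w in corrected if w.group == "total_killing"]
    live_thr = calibrate_live_threshold(nt, factor=config.live_threshold_factor)
    dead_thr = None
    if any(lm.n_objects for _, lm in tk):
        dead_thr = calibrate_dead_threshold(
            [(w, lm) for w, lm in tk if lm.n_objects], factor=config.dead_threshold_factor
        )

    frames = [
        quantify_image_set(w, label_maps[w.well_id], live_thr, dead_thr)
        for w in corrected
    ]
    records = pd.concat(frames, ignore_index=True)
    if config.normalize:
        records = normalize_viability(
            records, records[records["group"] == "no_treatment"]
        )

    summaries = []
    for (group, dose), sub in records.groupby(
        ["group", records["dose"].fillna(-1.0)], sort=True
    ):
        summaries.append(summarize_group(sub))

    dose_fit = None
    treated = records[records["group"] == "treatment"].dropna(subset=["dose"])
    nt_records = records[records["group"] == "no_treatment"]
    if not treated.empty:
        med = treated.groupby(["dose", "well_id"])["viability"].median().reset_index()
        zero = nt_records.groupby("well_id")["viability"].median().reset_index()
        zero.insert(0, "dose", 0.0)
        curve = pd.concat([zero, med], ignore_index=True).dropna(subset=["viability"])
        if np.unique(curve["dose"]).size >= 4:
            dose_fit = dose_response_fit(
                curve["dose"].to_numpy(),
                curve["viability"].to_numpy(),
                model=config.dose_response_model,
            )

    report = {
        "software": {"name": "vitalseg", "version": __version__},
        "experiment_id": manifest.experiment_id,
        "pixel_area": manifest.pixel_area,
        "parameters": config.to_dict(),
        "background": {
            "live": background.live_background,
            "dead": background.dead_background,
            "n_images": background.n_images,
        },
        "live_threshold": {"raw_otsu": live_thr.raw_otsu, "factor": live_thr.factor, "value": live_thr.value},
        "dead_threshold": None
        if dead_thr is None
        else {"raw_otsu": dead_thr.raw_otsu, "factor": dead_thr.factor, "value": dead_thr.value},
        "object_counts": counts,
        "n_objects_total": int(records.shape[0]),
        "dose_response": None
        if dose_fit is None
        else {"model": dose_fit.model, "params": dose_fit.params, "rss": dose_fit.rss},
    }

    result = RunResult(
        records=records,
        summaries=summaries,
        background=background,
        live_threshold=live_thr,
        dead_threshold=dead_thr,
        dose_response=dose_fit,
        report=report,
        label_maps=label_maps,
    )
    if out_dir is not None:
        _write_artifacts(result, corrected, Path(out_dir), config)
    return result


def _write_artifacts(result: RunResult, wells, out_dir: Path, config: RunConfig) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    records = result.records.copy()
    # stable column order and float formatting -> byte-identical reruns
    records.to_csv(out_dir / "objects.csv", index=False, float_format="%.10g")
    rows = []
    for s in result.summaries:
        row = {"group": s.group, "dose": s.dose, "n_images": s.n_images}
        for m, v in s.mean_of_medians.items():
            row[f"{m}_mean_of_medians"] = v
            row[f"{m}_sd"] = s.sd[m]
            row[f"{m}_sem"] = s.sem[m]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "group_summary.csv", index=False, float_format="%.10g")
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    if config.render_maps:
        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        by_well = dict(tuple(records.groupby("well_id")))
        for w in wells:
            lm = result.label_maps[w.well_id]
            rec = by_well.get(w.well_id)
            if rec is None or lm.n_objects == 0:
                continue
            heat = render_viability_heatmap(lm, rec)
            live_map = render_live_area_map(lm, w.live, result.live_threshold)
            iio.imwrite(maps_dir / f"{w.well_id}_viability.png", heat)
            iio.imwrite(maps_dir / f"{w.well_id}_live_area.png", live_map)


def run_simulate(out_dir: str | Path, seed: int = 0, preset_name: str = "paper_like", **kwargs) -> Path:
    """Simulate a complete analyzable plate; returns the manifest path.

    The ``paper_like`` preset writes no-treatment and total-killing
    controls plus a three-level dose series of a size-dependent treatment.
    """
    from .synth import simulate_plate

    if preset_name != "paper_like":
        raise ValueError(f"unknown plate preset: {preset_name!r}")
    return simulate_plate(out_dir, seed=seed, **kwargs)
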