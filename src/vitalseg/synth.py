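"""Ground-truthed synthetic plate scenes.

Generates scenes that emulate the phenotype of heterotypic 3D tumor
cultures in transmitted-light + live/dead fluorescence imaging:

* dark organoid silhouettes of heterogeneous, non-spherical (lobed) shape
  on a bright, non-uniformly illuminated background;
* calcein fluorescence proportional to local viability with a core–shell
  gradient (lower viability toward the center, as in hypoxic cores), PI
  fluorescence complementary to it;
* sub-threshold debris specks and detached bright single cells in the
  inter-organoid space;
* out-of-focus organoids: sharp in brightfield but strongly attenuated and
  blurred in fluorescence.

Every scene carries its ground truth (per-organoid mask, true area, true
per-pixel viability, focus flag) so each pipeline stage can be scored
against it.  A fixed seed pins every random draw.

The renderer is intentionally not a full optical model: the pipeline under
test is intensity-ratio based, so illumination gradients, noise and
attenuation carry all the test power a PSF would add.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageSet

_TWO31 = 2**31


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene (all randomness pinned by seed)."""

    shape: tuple[int, int] = (512, 512)
    pixel_area: float = 38.62  # µm²/px; 1950 µm² size cut ≈ 50 px
    n_organoids: int = 25
    # log-normal true-area distribution, in µm²
    area_median_um2: float = 20000.0
    area_sigma_log: float = 0.45
    lobe_range: tuple[int, int] = (1, 4)  # ellipse lobes per organoid
    axis_ratio_range: tuple[float, float] = (1.0, 2.2)
    core_shell_depth: float = 0.2  # viability drop toward the center, in [0,1]
    viability_range: tuple[float, float] = (1.0, 1.0)  # per-organoid base
    illumination_range: tuple[float, float] = (0.7, 1.3)  # multiplicative ramp
    bf_background: float = 1000.0  # a.u.
    bf_silhouette: float = 0.5  # organoid brightfield = silhouette × local bg
    fluor_background: tuple[float, float] = (100.0, 100.0)  # live, dead a.u.
    fluor_gain: float = 1000.0  # a.u. per unit viability occupancy
    noise_sd: float = 10.0  # additive Gaussian sd, a.u.
    noise_signal_coeff: float = 0.01  # + coeff × signal, a.u.
    debris_per_mm2: float = 3.0  # dark specks, each < half the size cut
    detached_per_mm2: float = 6.0  # bright fluorescent singles
    out_of_focus_fraction: float = 0.0
    oof_attenuation: float = 15.0  # fluorescence divided by this (≥ 10)
    oof_blur_sigma: float = 4.0  # px
    min_separation_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organoids < 0:
            raise ValueError("n_organoids must be >= 0")
        if not 0 <= self.out_of_focus_fraction <= 1:
            raise ValueError("out_of_focus_fraction must be in [0, 1]")
        if not 0 <= self.core_shell_depth <= 1:
            raise ValueError("core_shell_depth must be in [0, 1]")
        if min(self.debris_per_mm2, self.detached_per_mm2) < 0:
            raise ValueError("densities must be >= 0")

    @property
    def area_mm2(self) -> float:
        return self.shape[0] * self.shape[1] * self.pixel_area / 1e6


@dataclass
class OrganoidTruth:
    id: int
    true_area_um2: float
    true_mean_viability: float
    in_focus: bool
    centroid: tuple[float, float]


@dataclass
class GroundTruthScene:
    """True geometry and viability of a synthetic scene.

    ``labels`` holds the pairwise-disjoint organoid masks (0 = background);
    ``viability`` is the per-pixel true viability field, 0 outside objects.
    """

    labels: np.ndarray
    viability: np.ndarray
    organoids: list[OrganoidTruth]
    config: SceneConfig

    def mask(self, organoid_id: int) -> np.ndarray:
        return self.labels == organoid_id

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "object_id": o.id,
                    "true_area_um2": o.true_area_um2,
                    "true_mean_viability": o.true_mean_viability,
                    "in_focus": o.in_focus,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                }
                for o in self.organoids
            ]
        )


def _raster_union(specs, ratio: float, scale: float) -> np.ndarray:
    """Rasterize a union of ellipse lobes at the given scale, cropped to
    its bounding box.  ``specs`` rows: (u, v, shrink, theta) with lobe
    centers at (u·b, v·a) in the primary ellipse's frame."""
    a, b = scale * ratio, scale
    pad = int(np.ceil(1.9 * max(a, b))) + 2
    yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1].astype(float)
    mask = np.zeros(yy.shape, dtype=bool)
    for u, v, shrink, theta in specs:
        cy, cx = u * b, v * a
        ca, cb = a * shrink, b * shrink
        yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
        xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        mask |= (xr / ca) ** 2 + (yr / cb) ** 2 <= 1.0
    rows, cols = np.any(mask, axis=1), np.any(mask, axis=0)
    r0, r1 = rows.argmax(), len(rows) - rows[::-1].argmax()
    c0, c1 = cols.argmax(), len(cols) - cols[::-1].argmax()
    return mask[r0:r1, c0:c1]


def _lobed_mask(rng: np.random.Generator, target_px: float, cfg: SceneConfig) -> np.ndarray:
    """Union of overlapping ellipses with ~target_px pixels.

    The lobe layout is drawn once in a unit frame, rasterized at a trial
    scale, then re-rasterized after one corrective rescale so the union's
    pixel count lands on the target area to within rasterization error.
    """
    n_lobes = int(rng.integers(cfg.lobe_range[0], cfg.lobe_range[1] + 1))
    ratio = float(rng.uniform(*cfg.axis_ratio_range))
    specs = [(0.0, 0.0, 1.0, float(rng.uniform(0, np.pi)))]
    for _ in range(n_lobes - 1):
        specs.append(
            (
                float(rng.uniform(-0.7, 0.7)),
                float(rng.uniform(-0.7, 0.7)),
                float(rng.uniform(0.35, 0.7)),
                float(rng.uniform(0, np.pi)),
            )
        )
    s0 = np.sqrt(target_px / (np.pi * ratio))
    area0 = _raster_union(specs, ratio, s0).sum()
    s1 = s0 * np.sqrt(target_px / max(area0, 1.0))
    return _raster_union(specs, ratio, s1)


def generate_scene(config: SceneConfig) -> GroundTruthScene:
    """Draw organoid geometries and viability fields reproducibly.

    Shapes are unions of overlapping ellipses (lobed, non-spherical), areas
    follow the configured log-normal, and the viability field applies a
    core–shell profile: v(p) = base × (1 − depth × c(p)) where c is the
    normalized distance from the boundary (1 at the core), so viability is
    lowest at the center.  Placement keeps organoid masks pairwise disjoint
    with a small separation margin; an overcrowded configuration runs out
    of placement retries and raises.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    labels = np.zeros((h, w), dtype=np.int32)
    viab = np.zeros((h, w), dtype=np.float64)
    organoids: list[OrganoidTruth] = []
    mu = np.log(config.area_median_um2)
    sep = max(1, int(config.min_separation_px))

    for oid in range(1, config.n_organoids + 1):
        target_um2 = float(rng.lognormal(mu, config.area_sigma_log))
        target_px = target_um2 / config.pixel_area
        local = _lobed_mask(rng, target_px, config)
        lh, lw = local.shape
        if lh >= h or lw >= w:
            raise ValueError("organoid larger than the scene; reduce area_median_um2")
        placed = False
        occupied = ndi.binary_dilation(labels > 0, iterations=sep) if oid > 1 else None
        for _ in range(60):
            r0 = int(rng.integers(0, h - lh))
            c0 = int(rng.integers(0, w - lw))
            region = slice(r0, r0 + lh), slice(c0, c0 + lw)
            if occupied is not None and np.any(occupied[region] & local):
                continue
            labels[region][local] = oid
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place organoid {oid} after 60 retries: scene overcrowded"
            )
        # core-shell viability profile on the local mask
        edt = ndi.distance_transform_edt(local)
        core = edt / edt.max() if edt.max() > 0 else edt
        base = rng.uniform(*config.viability_range)
        v_local = base * (1.0 - config.core_shell_depth * core)
        viab[region][local] = v_local[local]
        cy, cx = ndi.center_of_mass(local)
        organoids.append(
            OrganoidTruth(
                id=oid,
                true_area_um2=float(local.sum() * config.pixel_area),
                true_mean_viability=float(v_local[local].mean()),
                in_focus=True,
                centroid=(r0 + cy, c0 + cx),
            )
        )

    # mark the out-of-focus subset
    if config.out_of_focus_fraction > 0 and organoids:
        n_oof = int(round(config.out_of_focus_fraction * len(organoids)))
        oof_ids = rng.choice([o.id for o in organoids], size=n_oof, replace=False)
        for o in organoids:
            if o.id in set(int(i) for i in oof_ids):
                o.in_focus = False
    return GroundTruthScene(labels=labels, viability=viab, organoids=organoids, config=config)


def apply_treatment(
    scene: GroundTruthScene,
    model: str,
    dose: float,
    alpha: float = 0.05,
    gamma: float = 1.0,
    area_ref: float | None = None,
) -> GroundTruthScene:
    """Scale the true viability field to emulate a treatment effect.

    ``uniform_kill`` multiplies every organoid's viability by exp(−α·dose)
    regardless of size (chemotherapy-like homogeneous action);
    ``size_dependent_kill`` multiplies by exp(−α·dose·(A_ref/A)^γ), hitting
    small organoids harder (photodynamic-therapy-like sparing of large
    organoids).  Dose 0 is the identity.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if model not in ("uniform_kill", "size_dependent_kill"):
        raise ValueError(f"unknown treatment model: {model!r}")
    if area_ref is None:
        areas = [o.true_area_um2 for o in scene.organoids]
        area_ref = float(np.median(areas)) if areas else 1.0
    viab = scene.viability.copy()
    organoids = []
    for o in scene.organoids:
        if model == "uniform_kill":
            factor = float(np.exp(-alpha * dose))
        else:
            factor = float(np.exp(-alpha * dose * (area_ref / o.true_area_um2) ** gamma))
        m = scene.labels == o.id
        viab[m] *= factor
        organoids.append(dataclasses.replace(o, true_mean_viability=o.true_mean_viability * factor))
    return GroundTruthScene(
        labels=scene.labels, viability=viab, organoids=organoids, config=scene.config
    )


def _illumination(cfg: SceneConfig) -> np.ndarray:
    lo, hi = cfg.illumination_range
    h, w = cfg.shape
    ramp = (np.add.outer(np.arange(h), np.arange(w))) / float(h + w - 2)
    return lo + (hi - lo) * ramp


def _noise(rng: np.random.Generator, signal: np.ndarray, cfg: SceneConfig) -> np.ndarray:
    sd = cfg.noise_sd + cfg.noise_signal_coeff * signal
    return rng.normal(0.0, 1.0, signal.shape) * sd


def render(
    scene: GroundTruthScene,
    config: SceneConfig | None = None,
    group: str = "treatment",
    well_id: str = "well",
    dose: float | None = None,
    dose_unit: str | None = None,
    total_killing: bool = False,
    noise_seed: int | None = None,
) -> ImageSet:
    """Render a scene into a brightfield + live + dead ImageSet.

    Brightfield is the background level times the illumination ramp, with
    organoid (and debris) pixels darkened by the silhouette coefficient.
    Live fluorescence is background + gain × viability; dead is background
    + gain × (1 − viability) inside organoids.  Out-of-focus organoids keep
    their sharp brightfield silhouette but their fluorescence signal is
    divided by the attenuation factor and Gaussian-blurred.  A total-killing
    render forces the viability field to zero (fixed/permeabilized well).
    All channels are clipped at 0 after noise.
    """
    cfg = config or scene.config
    rng = np.random.default_rng(cfg.seed + 1 if noise_seed is None else noise_seed)
    h, w = cfg.shape
    fg = scene.labels > 0
    viab = np.zeros_like(scene.viability) if total_killing else scene.viability

    gradient = _illumination(cfg)
    bf = cfg.bf_background * gradient
    bf = np.where(fg, bf * cfg.bf_silhouette, bf)

    # debris: small dark specks (< half the size cut) in inter-organoid space
    n_debris = rng.poisson(cfg.debris_per_mm2 * cfg.area_mm2)
    debris = np.zeros((h, w), dtype=bool)
    for _ in range(n_debris):
        r, c = int(rng.integers(2, h - 2)), int(rng.integers(2, w - 2))
        rad = int(rng.integers(1, 3))
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        spot = yy**2 + xx**2 <= rad**2
        debris[r - rad : r + rad + 1, c - rad : c + rad + 1] |= spot
    debris &= ~fg
    bf = np.where(debris, cfg.bf_background * gradient * cfg.bf_silhouette, bf)

    # fluorescence signal fields (before background/noise)
    live_sig = cfg.fluor_gain * viab
    dead_sig = np.where(fg, cfg.fluor_gain * (1.0 - viab), 0.0)
    oof = [o for o in scene.organoids if not o.in_focus]
    for o in oof:
        m = scene.labels == o.id
        for sig in (live_sig, dead_sig):
            attenuated = np.where(m, sig / cfg.oof_attenuation, 0.0)
            sig[m] = 0.0
            sig += ndi.gaussian_filter(attenuated, cfg.oof_blur_sigma)

    # detached single cells: bright fluorescent loci between organoids
    n_cells = rng.poisson(cfg.detached_per_mm2 * cfg.area_mm2)
    for _ in range(n_cells):
        r, c = int(rng.integers(1, h - 1)), int(rng.integers(1, w - 1))
        if fg[r, c]:
            continue
        amp = cfg.fluor_gain * rng.uniform(0.8, 1.5)
        # on a fixed/permeabilized well every detached cell is PI-positive
        is_live = rng.random() < 0.7 and not total_killing
        channel = live_sig if is_live else dead_sig
        channel[r - 1 : r + 2, c - 1 : c + 2] += amp * 0.3
        channel[r, c] += amp

    live = cfg.fluor_background[0] + live_sig
    dead = cfg.fluor_background[1] + dead_sig
    bf = np.clip(bf + _noise(rng, bf, cfg), 0.0, None)
    live = np.clip(live + _noise(rng, live, cfg), 0.0, None)
    dead = np.clip(dead + _noise(rng, dead, cfg), 0.0, None)
    return ImageSet(
        brightfield=bf,
        live=live,
        dead=dead,
        pixel_area=cfg.pixel_area,
        well_id=well_id,
        group=group,
        dose=dose,
        dose_unit=dose_unit,
    )


# ---------------------------------------------------------------------------
# Named presets: the regimes cross-module tests and analyses are scored in.

def preset(name: str, seed: int = 0) -> SceneConfig:
    """Named scene regimes with pinned geometry.

    ``segmentation``: 1024² scene, ≥ 50 organoids, full ×0.7–1.3
    illumination ramp, debris and detached cells present, 15% of organoids
    out of focus — the regime segmentation recovery is scored in.

    ``quantification``: same geometry without out-of-focus organoids and
    with per-organoid base viability spread over [0.05, 0.95], the regime
    for viability-recovery scoring.

    ``control``: 512² untreated-well geometry (fully viable organoids,
    mild hypoxic-core depth) used for control wells and calibration.
    """
    if name == "segmentation":
        return SceneConfig(
            shape=(1024, 1024),
            n_organoids=55,
            out_of_focus_fraction=0.15,
            seed=seed,
        )
    if name == "quantification":
        return SceneConfig(
            shape=(1024, 1024),
            n_organoids=55,
            viability_range=(0.05, 0.95),
            core_shell_depth=0.0,
            out_of_focus_fraction=0.0,
            seed=seed,
        )
    if name == "control":
        return SceneConfig(shape=(512, 512), n_organoids=14, seed=seed)
    raise ValueError(f"unknown preset: {name!r}")


def simulate_plate(
    out_dir: str | Path,
    seed: int = 0,
    n_control: int = 3,
    n_tk: int = 2,
    doses: tuple[float, ...] = (5.0, 15.0, 40.0),
    wells_per_dose: int = 2,
    treatment_model: str = "size_dependent_kill",
    dose_unit: str = "J/cm2",
    scene_config: SceneConfig | None = None,
    experiment_id: str = "synthetic_plate",
) -> Path:
    """Write a complete analyzable plate: TIFFs + manifest + ground truth.

    Wells: ``n_control`` no-treatment, ``n_tk`` total-killing and
    ``wells_per_dose`` wells per dose level, each an independently drawn
    scene.  Returns the manifest CSV path; ground truth (per-organoid true
    area, true mean viability, focus flag) sits next to it.
    """
    from .io import write_image_set

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_cfg = scene_config or preset("control", seed)
    rows, truth_frames = [], []
    wells: list[tuple[str, str, float | None, bool]] = []
    wells += [(f"NT{i+1}", "no_treatment", None, False) for i in range(n_control)]
    wells += [(f"TK{i+1}", "total_killing", None, True) for i in range(n_tk)]
    for d in doses:
        wells += [
            (f"D{d:g}_{i+1}", "treatment", float(d), False)
            for i in range(wells_per_dose)
        ]

    for i, (well_id, group, dose, tk) in enumerate(wells):
        cfg = dataclasses.replace(base_cfg, seed=(seed * 1009 + 7 * i + 1) % _TWO31)
        scene = generate_scene(cfg)
        if group == "treatment":
            scene = apply_treatment(scene, treatment_model, dose)
        img = render(
            scene,
            cfg,
            group=group,
            well_id=well_id,
            dose=dose,
            dose_unit=dose_unit if dose is not None else None,
            total_killing=tk,
        )
        paths = write_image_set(img, out_dir / "images")
        rows.append(
            {
                "well_id": well_id,
                "group": group,
                "dose": dose,
                "dose_unit": dose_unit if dose is not None else None,
                "path_brightfield": paths["brightfield"].relative_to(out_dir).as_posix(),
                "path_live": paths["live"].relative_to(out_dir).as_posix(),
                "path_dead": paths["dead"].relative_to(out_dir).as_posix(),
                "pixel_area": cfg.pixel_area,
                "experiment_id": experiment_id,
            }
        )
        tt = scene.truth_table()
        tt.insert(0, "well_id", well_id)
        tt.insert(1, "group", group)
        tt.insert(2, "dose", np.nan if dose is None else float(dose))
        if tk:
            tt["true_mean_viability"] = 0.0
        truth_frames.append(tt)

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out_dir / "ground_truth.csv", index=False
    )
    return manifest_path
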