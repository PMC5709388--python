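"""Derived outputs: group summaries, distributions, fits and rendered maps.

Group summaries follow the "mean of the median value per image" convention:
the per-image median over objects is the robust per-well statistic, and
mean ± SD/SEM across images describes the group.  Dose-response curves are
least-squares fits, by default a three-parameter exponential decay
R(d) = plateau + (R0 − plateau)·exp(−k·d); pairwise relations between
readouts (e.g. viability vs organoid area) use ordinary least squares.

Rendered heatmaps are presentation artifacts — the scientific content lives
in the per-object CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Metrics summarized per group by default.
SUMMARY_METRICS = ("total_area", "frac_live_area", "viability")

#: Sentinel RGB for objects with undefined viability in heatmaps.
MISSING_COLOR = (255, 0, 255)


@dataclass
class GroupSummary:
    group: str
    dose: float | None
    n_images: int
    n_dropped_images: int
    per_image_medians: dict[str, list[float]]
    mean_of_medians: dict[str, float]
    sd: dict[str, float]
    sem: dict[str, float]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    stderr: float = float("nan")  # standard error of the slope

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


@dataclass
class DoseResponseFit:
    model: str
    params: dict[str, float]
    rss: float
    doses: np.ndarray
    responses: np.ndarray

    def predict(self, d):
        d = np.asarray(d, dtype=np.float64)
        if self.model == "linear":
            return self.params["slope"] * d + self.params["intercept"]
        p = self.params
        return p["plateau"] + (p["r0"] - p["plateau"]) * np.exp(-p["k"] * d)


def summarize_group(
    records: pd.DataFrame,
    metrics=SUMMARY_METRICS,
    image_col: str = "well_id",
    expected_images: int | None = None,
) -> GroupSummary:
    """Mean/SD/SEM of per-image medians for each metric.

    Missing values (undefined viabilities) are excluded from the medians.
    Images with zero objects cannot contribute a median; if
    ``expected_images`` is given, the shortfall is reported as dropped.
    """
    if records.empty:
        raise ValueError("summarize_group requires >= 1 image with >= 1 object")
    per_image = records.groupby(image_col)[list(metrics)].median()
    n = len(per_image)
    medians = {m: per_image[m].dropna().tolist() for m in metrics}
    mean = {m: float(np.mean(v)) if v else float("nan") for m, v in medians.items()}
    sd = {
        m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        for m, v in medians.items()
    }
    sem = {m: s / np.sqrt(len(medians[m])) if medians[m] else float("nan") for m, s in sd.items()}
    group = str(records["group"].iloc[0]) if "group" in records else ""
    dose = None
    if "dose" in records and records["dose"].notna().any():
        dose = float(records["dose"].iloc[0])
    return GroupSummary(
        group=group,
        dose=dose,
        n_images=n,
        n_dropped_images=max(0, (expected_images or n) - n),
        per_image_medians=medians,
        mean_of_medians=mean,
        sd=sd,
        sem=sem,
    )


def metric_histogram(values, bin_edges) -> np.ndarray:
    """Counts per bin; left-closed right-open bins, last bin closed."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(values, dtype=np.float64)
    counts, _ = np.histogram(values[np.isfinite(values)], bins=edges)
    return counts


def linear_fit(x, y) -> RegressionFit:
    """Ordinary least squares of y on x over finite pairs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("linear fit requires >= 3 finite pairs")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        stderr=float(res.stderr),
    )


def _exp_decay(params, d):
    r0, plateau, k = params
    return plateau + (r0 - plateau) * np.exp(-k * d)


def dose_response_fit(doses, responses, model: str = "exponential_decay") -> DoseResponseFit:
    """Least-squares dose-response fit.

    The exponential-decay model R(d) = plateau + (R0 − plateau)·exp(−k·d)
    with R0, plateau, k ≥ 0 is fitted from a fixed grid of initial decay
    rates (deterministic multi-start); the lowest residual sum of squares
    wins and ties go to the smallest k.  ``model="linear"`` delegates to
    :func:`linear_fit`.
    """
    d = np.asarray(doses, dtype=np.float64)
    r = np.asarray(responses, dtype=np.float64)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("doses and responses must be 1D and equally long")
    if not np.all(np.isfinite(d)) or not np.all(np.isfinite(r)):
        raise ValueError("doses and responses must be finite")

    if model == "linear":
        fit = linear_fit(d, r)
        rss = float(np.sum((fit.predict(d) - r) ** 2))
        return DoseResponseFit(
            "linear",
            {"slope": fit.slope, "intercept": fit.intercept},
            rss,
            d,
            r,
        )
    if model != "exponential_decay":
        raise ValueError(f"unknown dose-response model: {model!r}")

    n_distinct = np.unique(d).size
    if n_distinct < 4:  # three parameters need four distinct doses
        raise ValueError("exponential decay requires >= 4 distinct dose levels")

    scale = float(d.max()) if d.max() > 0 else 1.0
    order = np.argsort(d)
    r0_init = float(r[order[0]])
    plateau_init = float(r[order[-1]])
    best = None
    for k0 in (0.0, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0):
        x0 = np.array([max(r0_init, 0.0), max(plateau_init, 0.0), k0 / scale])
        sol = optimize.least_squares(
            lambda p: _exp_decay(p, d) - r,
            x0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        )
        rss = float(np.sum(sol.fun**2))
        if (
            best is None
            or rss < best[0] - 1e-12
            or (abs(rss - best[0]) <= 1e-12 and sol.x[2] < best[1].x[2])
        ):
            best = (rss, sol)
    rss, sol = best
    r0, plateau, k = (float(v) for v in sol.x)
    return DoseResponseFit(
        "exponential_decay", {"r0": r0, "plateau": plateau, "k": k}, rss, d, r
    )


def render_viability_heatmap(
    label_map,
    records: pd.DataFrame,
    column: str = "viability",
    cmap: str = "viridis",
    vmin: float = 0.0,
    vmax: float = 1.0,
) -> np.ndarray:
    """Paint each object with its (normalized) viability; background black.

    Values are mapped through a matplotlib colormap and quantized to 8-bit
    RGB; objects with undefined viability get a reserved sentinel color.
    A totally killed well therefore renders almost completely dark under
    the default map.
    """
    import matplotlib

    ids = set(records["object_id"].astype(int))
    if not ids.issuperset(label_map.object_ids):
        raise ValueError("records must cover every label id")
    colormap = matplotlib.colormaps[cmap]
    lut = np.zeros((label_map.n_objects + 1, 3), dtype=np.uint8)
    by_id = records.set_index(records["object_id"].astype(int))[column]
    for oid in label_map.object_ids:
        v = by_id.loc[oid]
        if np.isnan(v):
            lut[oid] = MISSING_COLOR
        else:
            t = np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
            lut[oid] = (np.asarray(colormap(float(t))[:3]) * 255).astype(np.uint8)
    return lut[label_map.labels]


def render_live_area_map(label_map, live, threshold) -> np.ndarray:
    """Binary map: 255 where an object pixel exceeds the live threshold."""
    live = np.asarray(live, dtype=np.float64)
    mask = label_map.foreground & (live > threshold.value)
    return (mask * 255).astype(np.uint8)
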