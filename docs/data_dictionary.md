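# Per-object table (`objects.csv`)

One row per indexed organoid. The object index (`object_id`) is unique
within a well and stable across reruns on identical inputs.

| column                 | unit  | meaning |
|------------------------|-------|---------|
| `well_id`              | —     | well/field identifier from the manifest |
| `group`                | —     | `no_treatment`, `total_killing` or `treatment` |
| `dose`                 | manifest `dose_unit` | treatment dose; empty for controls |
| `dose_unit`            | —     | unit label for `dose` |
| `object_id`            | —     | organoid index in the well's final label map (1..N) |
| `area_px`              | px    | pixel count of the object |
| `total_area`           | µm²   | `area_px × pixel_area` |
| `mean_live`            | a.u.  | mean background-corrected calcein-AM intensity over the object |
| `mean_dead`            | a.u.  | mean background-corrected PI intensity over the object |
| `viability`            | —     | `mean_live / (mean_live + mean_dead)` ∈ [0, 1]; empty if both intensities are 0 |
| `live_area`            | µm²   | area of object pixels with live intensity strictly above the live threshold |
| `frac_live_area`       | —     | `live_area / total_area` ∈ [0, 1] |
| `dead_area`            | µm²   | dead-channel analog of `live_area` (empty when no dead threshold was calibrated) |
| `frac_dead_area`       | —     | `dead_area / total_area` |
| `centroid_row`         | px    | 0-based row of the object centroid |
| `centroid_col`         | px    | 0-based column of the object centroid |
| `normalized_viability` | —     | `viability / median(no-treatment viability)`, if normalization is enabled |

# Group summary table (`group_summary.csv`)

One row per (group, dose). For each metric (`total_area`,
`frac_live_area`, `viability`): `<metric>_mean_of_medians` is the mean of
the per-image medians, `<metric>_sd` the sample standard deviation
(ddof = 1) and `<metric>_sem` = SD/√n of those medians. `n_images` counts
images contributing at least one object.

# Run report (`report.json`)

Software version, experiment id, pixel area, every run parameter, the
background estimate (per channel, number of control images), the raw and
scaled live/dead thresholds, per-well object counts per stage, and the
dose-response fit (model, parameters, residual sum of squares) when one
was computed.
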