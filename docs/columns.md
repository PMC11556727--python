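# Measurement table columns

## Per-spheroid table (`per_spheroid.csv`)

| column | units | meaning |
|---|---|---|
| `spheroid_id` | – | label id of the spheroid in the stack |
| `volume_um3` | µm³ | voxel count × voxel volume of the spheroid region |
| `surface_area_um2` | µm² | marching-cubes mesh area of the region |
| `sphericity` | – | Wadell Ψ = π^{1/3}(6V)^{2/3}/A, unclipped |
| `n_nuclei` | – | nuclei whose centroid lies inside the region |
| `width_um` | µm | maximum Feret diameter of the XY projection |
| `height_um` | µm | z extent of the region |

The spheroid aspect ratio reported in summaries is `100 · height / width`.

## Per-cell table (`per_cell.csv`)

One row per kept (gated) cell. `<role>` is one of the analyzed organelle
channels (`golgi`, `endosome`, `lysosome`, `egfp`).

| column | units | meaning |
|---|---|---|
| `cell_id` | – | cell label (equals its nucleus label) |
| `spheroid_id` | – | owning spheroid |
| `<role>_volume_um3` | µm³ | total volume of the cell's fragments |
| `<role>_surface_area_um2` | µm² | sum of per-fragment mesh areas |
| `<role>_fragment_count` | – | fragments assigned to the cell (post size filter) |
| `<role>_footprint_um2` | µm² | distinct XY pixel columns containing ≥ 1 fragment voxel, × pixel area |
| `egfp_mean_intensity` | counts | mean EGFP intensity over the cell |
| `texture_plane_bright` | – | mean plane_bright over the cytoplasm / mean EGFP intensity |
| `texture_saddle` | – | mean saddle over the cytoplasm / mean EGFP intensity |

## Per-fragment tables (`fragments_<role>.csv`)

One row per segmented organelle fragment: `fragment_id`, `cell_id` (0 if
unassigned), `volume_um3`, and the centroid `z_um`, `y_um`, `x_um`.

## Prescan tables

`prescan_records_*.csv`: `record_id`, `centroid_um` (y, x in well
coordinates), `area_um2`, `width_um` (minimum Feret), `roundness`
(4πA/P², Crofton perimeter), `border_touching`.

`rescan_targets_*.csv`: `source_record_id`, `center_um`, `extent_um`
(requested z, y, x stack extent).

## Phantom truth tables (`phantom_*_truth.csv`)

Per generated cell: `cell_id`, `<channel>_volume_um3` and
`<channel>_fragment_count` computed exactly from the label volumes, the
EGFP class (`egfp_class`), and — when an EGFP channel is rendered —
`egfp_footprint_um2` and `egfp_volume_um3`.
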