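"""Pipeline orchestration: the analysis chain and the CLI-facing modes.

``analyze_stack`` is the core chain — spheroid → nuclei → cells → organelle
sets → per-cell and per-spheroid feature tables — used both by the CLI and
by the end-to-end phantom recovery machinery (:mod:`spheroquant.recovery`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, io, organelles, segment3d
from .config import AnalysisParams, RunConfig
from .phantoms import (PhantomSpec, apply_phenotype, build_spheroid_phantom,
                       paper_default, render)
from .prescan import detect_spheroids_2d, select_rescan_targets
from .stack import ImageStack
from .stats import assay_report

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the 3D chain produces for one stack."""

    spheroid_labels: np.ndarray
    cells: segment3d.CellPartition
    organelle_sets: list[organelles.OrganelleSet]
    kept_cell_ids: np.ndarray
    spheroid_measures: pd.DataFrame
    per_cell: pd.DataFrame


def analyze_stack(stack: ImageStack, params: AnalysisParams | None = None,
                  organelle_routes: dict[str, str] | None = None,
                  compute_texture: bool = True) -> AnalysisResult:
    """Run the full 3D chain on one multichannel stack.

    ``organelle_routes`` maps channel names present in the stack to either
    ``"gaussian"`` (large-structure route) or ``"spots"`` (spot-bright
    route); channels absent from the stack are skipped silently.
    ``compute_texture=False`` skips the EGFP PLS texture maps (they are only
    needed when texture features are being compared).
    """
    params = params or AnalysisParams()
    routes = organelle_routes or {"golgi": "gaussian", "endosome": "spots",
                                  "lysosome": "spots", "egfp": "gaussian"}
    sph = segment3d.segment_spheroid(
        stack, channel=params.spheroid_channel, sigma_um=params.spheroid_sigma_um,
        min_volume_um3=params.spheroid_min_volume_um3,
        threshold_method=params.spheroid_threshold)
    nuclei = segment3d.segment_nuclei(
        stack, sph > 0, channel=params.spheroid_channel,
        sigma_um=params.nuclei_sigma_um, h_um=params.nuclei_h_um,
        volume_window_um3=params.nuclei_volume_window_um3)
    cells = segment3d.segment_cells(
        stack, sph, nuclei, channel=params.spheroid_channel,
        sigma_um=params.nuclei_sigma_um,
        residual_fraction=params.cytoplasm_residual_fraction)
    kept = segment3d.gate_egfp(cells, stack, mode=params.egfp_gate_mode)

    osets: list[organelles.OrganelleSet] = []
    for chan, route in routes.items():
        if not stack.has_channel(chan):
            continue
        if route == "gaussian":
            osets.append(organelles.segment_large_organelle(
                stack, chan, cells, sigma_um=params.golgi_sigma_um,
                min_volume_um3=params.golgi_min_volume_um3,
                split_h_fraction=params.golgi_split_h_fraction))
        elif route == "spots":
            osets.append(organelles.detect_spots(
                stack, chan, cells, sigma_spot_um=params.spot_sigma_um,
                k_mad=params.spot_k_mad,
                volume_window_um3=params.spot_volume_window_um3))
        else:
            raise ValueError(f"unknown organelle route {route!r} for {chan}")

    pls = None
    if compute_texture and stack.has_channel("egfp"):
        eigs = organelles.hessian_eigs(stack, "egfp", params.texture_sigma_um)
        pls = organelles.pls_maps(eigs)

    sph_rows = []
    for sid in np.unique(sph):
        if sid == 0:
            continue
        m = features.measure_spheroid(sph, nuclei, stack.voxel_size,
                                      spheroid_id=int(sid))
        sph_rows.append(vars(m))
    per_cell = features.measure_cell_organelles(
        cells, osets, stack.voxel_size, stack=stack, pls=pls)
    if len(per_cell):
        per_cell = per_cell[per_cell["cell_id"].isin(kept)].reset_index(drop=True)
    return AnalysisResult(
        spheroid_labels=sph, cells=cells, organelle_sets=osets,
        kept_cell_ids=kept,
        spheroid_measures=pd.DataFrame(sph_rows), per_cell=per_cell)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, mode: str) -> dict:
    """Execute one pipeline mode; returns a dict of artifact paths.

    Modes: phantom-generate, prescan, analyze-3d, assay-compare. Failures
    raise :class:`StageError` naming the stage.
    """
    if mode not in ("phantom-generate", "prescan", "analyze-3d",
                    "assay-compare"):
        raise StageError(mode, ValueError(f"unknown mode {mode!r}"))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline mode=%s seed=%d output=%s", mode, config.seed, out)
    artifacts: dict[str, list[str]] = {"tables": [], "images": []}
    try:
        if mode == "phantom-generate":
            _mode_phantom_generate(config, out, artifacts)
        elif mode == "prescan":
            _mode_prescan(config, out, artifacts)
        elif mode == "analyze-3d":
            _mode_analyze3d(config, out, artifacts)
        elif mode == "assay-compare":
            _mode_assay_compare(config, out, artifacts)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(mode, exc) from exc
    return artifacts


def _phantom_spec_for(config: RunConfig, i: int) -> PhantomSpec:
    seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
    spec = paper_default(seed=seed, egfp_model=config.egfp_model,
                         channels=("golgi", "endosome", "lysosome"))
    return replace(spec, phenotype=config.phenotype)


def _mode_phantom_generate(config: RunConfig, out: Path, artifacts: dict) -> None:
    for i in range(config.n_phantoms):
        spec = _phantom_spec_for(config, i)
        scene, gt = build_spheroid_phantom(spec)
        rendered = render(scene, spec.optics, seed=spec.seed)
        stack_path = out / f"phantom_{i:03d}.ome.tif"
        io.write_stack(rendered, stack_path)
        labels = ImageStack(
            voxels=np.stack([gt.nuclei_labels, gt.cell_labels]).astype(np.uint16),
            voxel_size=spec.voxel_size, channel_names=["nuclei_labels", "cell_labels"])
        labels_path = out / f"phantom_{i:03d}_labels.ome.tif"
        io.write_stack(labels, labels_path)
        truth_path = out / f"phantom_{i:03d}_truth.csv"
        io.write_measurements(gt.per_cell_truth, truth_path)
        artifacts["images"] += [str(stack_path), str(labels_path)]
        artifacts["tables"].append(str(truth_path))


def _mode_prescan(config: RunConfig, out: Path, artifacts: dict) -> None:
    for i, path in enumerate(config.input_paths):
        image, px = io.read_image2d(path)
        records = detect_spheroids_2d(image, pixel_size_um=px or config.pixel_size_um)
        targets = select_rescan_targets(records,
                                        max_per_well=config.prescan_max_per_well)
        rec_path = out / f"prescan_records_{i:03d}.csv"
        io.write_measurements([vars(r) for r in records], rec_path)
        tgt_path = out / f"rescan_targets_{i:03d}.csv"
        io.write_measurements([vars(t) for t in targets], tgt_path)
        artifacts["tables"] += [str(rec_path), str(tgt_path)]


def _mode_analyze3d(config: RunConfig, out: Path, artifacts: dict) -> None:
    all_cells = []
    all_spheroids = []
    for i, path in enumerate(config.input_paths):
        stack = io.read_stack(path)
        result = analyze_stack(stack, params=config.params,
                               organelle_routes=config.organelle_routes)
        pc = result.per_cell.copy()
        pc.insert(0, "stack", Path(path).name)
        all_cells.append(pc)
        sm = result.spheroid_measures.copy()
        sm.insert(0, "stack", Path(path).name)
        all_spheroids.append(sm)
    cell_path = out / "per_cell.csv"
    sph_path = out / "per_spheroid.csv"
    io.write_measurements(pd.concat(all_cells, ignore_index=True), cell_path)
    io.write_measurements(pd.concat(all_spheroids, ignore_index=True), sph_path)
    artifacts["tables"] += [str(cell_path), str(sph_path)]
    for oset in result.organelle_sets:  # per-fragment tables, last stack
        frag_path = out / f"fragments_{oset.role}.csv"
        io.write_measurements(organelles.fragment_table(oset, stack.voxel_size),
                              frag_path)
        artifacts["tables"].append(str(frag_path))


def _mode_assay_compare(config: RunConfig, out: Path, artifacts: dict) -> None:
    if len(config.input_paths) != 2:
        raise ValueError("assay-compare needs exactly two per-cell tables "
                         "(control, treated)")
    control = io.read_measurements(config.input_paths[0])
    treated = io.read_measurements(config.input_paths[1])
    tables = []
    lines = []
    for col in config.compare_columns:
        if col not in control.columns or col not in treated.columns:
            raise ValueError(f"column {col!r} missing from an input table")
        tab, text = assay_report(control[col].dropna(), treated[col].dropna(),
                                 "control", "treated")
        tab.insert(0, "measure", col)
        tables.append(tab)
        lines.append(f"{col}: {text}")
    rep_path = out / "assay_report.csv"
    io.write_measurements(pd.concat(tables, ignore_index=True), rep_path)
    txt_path = out / "assay_report.txt"
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    artifacts["tables"] += [str(rep_path), str(txt_path)]
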