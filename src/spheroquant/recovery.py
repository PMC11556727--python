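"""End-to-end recovery runs: generate phantom arms, push them through the
full analysis chain, and summarize the quantities the platform reports.

This is the machinery behind reproducibility checks: the phantom generator
encodes the study conditions as ground truth, and the identical pipeline is
run on rendered (blurred, noisy) stacks for a control arm and a
drug-phenotype arm built from matched seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import AnalysisParams
from .phantoms import build_spheroid_phantom, paper_default, render
from .pipeline import AnalysisResult, analyze_stack


def phantom_seed(base_seed: int, index: int) -> int:
    """Deterministic per-phantom seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), int(index)])
               .generate_state(1)[0] % (2 ** 31))


def analyze_phantom(spec, params: AnalysisParams | None = None,
                    routes: dict[str, str] | None = None,
                    compute_texture: bool = False) -> tuple[AnalysisResult, object]:
    """Build, render and analyze one phantom; returns (result, ground_truth)."""
    scene, gt = build_spheroid_phantom(spec)
    rendered = render(scene, spec.optics, seed=spec.seed)
    result = analyze_stack(rendered, params=params, organelle_routes=routes,
                           compute_texture=compute_texture)
    return result, gt


def run_arm(base_seed: int, n_phantoms: int, phenotype: str = "control",
            channels: tuple[str, ...] = ("golgi",),
            egfp_model: str = "none",
            params: AnalysisParams | None = None,
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one assay arm of paper-default phantoms through the pipeline.

    Returns (per_cell, per_spheroid) tables pooled across phantoms. Arms
    built from the same ``base_seed`` use matched per-phantom seeds, so a
    control and a drug arm differ only in the phenotype transformation.
    """
    cells = []
    spheroids = []
    for i in range(n_phantoms):
        seed = phantom_seed(base_seed, i)
        spec = paper_default(seed=seed, egfp_model=egfp_model, channels=channels)
        spec = replace(spec, phenotype=phenotype)
        result, _ = analyze_phantom(spec, params=params)
        pc = result.per_cell.copy()
        pc.insert(0, "phantom", i)
        cells.append(pc)
        sm = result.spheroid_measures.copy()
        sm.insert(0, "phantom", i)
        spheroids.append(sm)
    return (pd.concat(cells, ignore_index=True),
            pd.concat(spheroids, ignore_index=True))


def recovery_summary(base_seed: int, n_phantoms: int = 20,
                     params: AnalysisParams | None = None) -> dict[str, dict]:
    """Recompute the platform's headline quantities from scratch.

    Control arm (Golgi + endosome channels + Rab6A EGFP) and a matched BFA
    arm (Golgi + Rab6A EGFP) are generated, rendered and analyzed; the
    summary reports, per quantity, the measured value and the number of
    cells (or spheroids) it was computed from:

    - golgi_volume_median_um3: median per-cell total Golgi volume (control)
    - endosome_area_median_um2: median per-cell total endosome surface area
    - golgi_fragment_fold_bfa: ratio of median per-cell Golgi fragment
      counts, BFA over control
    - rab6a_footprint_fold_bfa: ratio of mean per-cell EGFP-Rab6A footprint
      areas, BFA over control
    - aspect_ratio_percent: median of 100 x spheroid height / width (control)
    """
    control_cells, control_sph = run_arm(
        base_seed, n_phantoms, phenotype="control",
        channels=("golgi", "endosome"), egfp_model="rab6a_golgi", params=params)
    bfa_cells, _ = run_arm(
        base_seed, n_phantoms, phenotype="bfa",
        channels=("golgi",), egfp_model="rab6a_golgi", params=params)

    def entry(value, n):
        return {"value": float(value), "n": int(n)}

    ctrl_frag = control_cells["golgi_fragment_count"]
    bfa_frag = bfa_cells["golgi_fragment_count"]
    ctrl_fp = control_cells["egfp_footprint_um2"]
    bfa_fp = bfa_cells["egfp_footprint_um2"]
    aspect = 100.0 * control_sph["height_um"] / control_sph["width_um"]
    return {
        "golgi_volume_median_um3": entry(
            control_cells["golgi_volume_um3"].median(), len(control_cells)),
        "endosome_area_median_um2": entry(
            control_cells["endosome_surface_area_um2"].median(), len(control_cells)),
        "golgi_fragment_fold_bfa": entry(
            bfa_frag.median() / ctrl_frag.median(),
            min(len(bfa_cells), len(control_cells))),
        "rab6a_footprint_fold_bfa": entry(
            bfa_fp.mean() / ctrl_fp.mean(),
            min(len(bfa_cells), len(control_cells))),
        "aspect_ratio_percent": entry(aspect.median(), len(control_sph)),
    }
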