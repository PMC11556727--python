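"""Run configuration: plain-YAML, fully defaulted, unknown keys rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisParams:
    """All segmentation and filter parameters, with the 63x-emulation
    defaults. Smoothing scales and thresholds are in physical units (μm)."""

    spheroid_channel: str = "nuclei"
    spheroid_sigma_um: float = 3.0
    spheroid_min_volume_um3: float = 1.0e4
    # lowest threshold of a 3-class Otsu: the stack histogram is trimodal
    # (background / residual-stain rim / nuclear interior) and a 2-class
    # threshold erodes the spheroid boundary
    spheroid_threshold: str = "multiotsu3"
    # at 0.5 μm the smoothing suppresses voxel noise without inflating the
    # nuclear masks (1 μm dilates them ~30% and fuses touching nuclei)
    nuclei_sigma_um: float = 0.5
    # seed-merging depth on the distance transform; 0.5 μm separates nuclei
    # that touch (deformable packing) where 1 μm fuses them
    nuclei_h_um: float = 0.5
    nuclei_volume_window_um3: tuple[float, float] = (65.0, 1500.0)
    cytoplasm_residual_fraction: float = 0.08
    # Golgi-class structures: Gaussian + Otsu route. The smoothing scale is
    # matched to the rendered PSF so sub-micron drug-induced fragments are
    # not fused by over-smoothing.
    # smoothing below the PSF scale: at 63x/1.15 NA the rendered PSF already
    # band-limits the image, and extra smoothing fuses sub-micron fragments
    # along z (1 μm steps) — so the route smooths only enough to suppress
    # single-voxel noise
    golgi_sigma_um: float = 0.2
    # drug-fragmented Golgi pieces are ~0.5 μm³; a filter near that size
    # would discard watershed-split halves, so the profile keeps pieces
    # down to one voxel
    golgi_min_volume_um3: float = 0.1
    golgi_split_h_fraction: float = 0.08
    # endosome/lysosome-class structures: spot-bright route. The scale is
    # matched to the lateral width of a PSF-blurred punctum (~0.3 μm)
    spot_sigma_um: float = 0.35
    spot_k_mad: float = 6.0
    spot_volume_window_um3: tuple[float, float] = (0.02, 30.0)
    egfp_gate_mode: str = "parental"   # parental | gating
    texture_sigma_um: float = 0.5


@dataclass
class RunConfig:
    """Top-level configuration for the command-line pipeline."""

    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "spheroquant_out"
    channel_roles: dict[str, str] = field(default_factory=lambda: {
        "nuclei": "nuclei", "egfp": "egfp", "organelle": "golgi"})
    organelle_routes: dict[str, str] = field(default_factory=lambda: {
        "golgi": "gaussian", "endosome": "spots", "lysosome": "spots",
        "egfp": "gaussian"})
    params: AnalysisParams = field(default_factory=AnalysisParams)
    # phantom generation (phantom-generate mode)
    n_phantoms: int = 2
    phenotype: str = "control"
    egfp_model: str = "none"
    # prescan mode
    pixel_size_um: float = 3.0
    prescan_max_per_well: int = 10
    # assay-compare mode
    compare_columns: list[str] = field(default_factory=lambda: [
        "golgi_volume_um3", "golgi_fragment_count"])
    seed: int = 0


def _from_mapping(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if f.name == "params":
            value = _from_mapping(AnalysisParams, value or {}, key)
        elif isinstance(value, list) and "tuple" in str(f.type):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise with the key name."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root in {path} must be a mapping")
    return _from_mapping(RunConfig, data, str(path))


def save_config(config: RunConfig, path: str | Path) -> None:
    def _clean(obj):
        if dataclasses.is_dataclass(obj):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_clean(config), fh, sort_keys=False)
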