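"""YAML/JSON configuration for scenes, protocols and full pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .phantom import (
    AcquisitionProtocol,
    ExcitationLight,
    Fluorophore,
    SceneSpec,
    StainRegion,
    default_lights,
    make_protocol,
)


def protocol_from_config(cfg: dict | None) -> AcquisitionProtocol:
    """Build a protocol from its config mapping (missing keys use the
    standard 3-light, 420-720/20 nm grid)."""
    cfg = dict(cfg or {})
    lights_cfg = cfg.get("lights")
    if lights_cfg is None:
        lights = default_lights()
    else:
        lights = [
            ExcitationLight(
                name=l["name"],
                center_wavelength=float(l["center_nm"]),
                bandwidth=float(l.get("bandwidth_nm", 25.0)),
                relative_intensity=int(l.get("intensity", 255)),
            )
            for l in lights_cfg
        ]
    return make_protocol(
        lights,
        filter_min=float(cfg.get("filter_min", 420.0)),
        filter_max=float(cfg.get("filter_max", 720.0)),
        increment=float(cfg.get("increment", 20.0)),
        frame_height=int(cfg.get("frame_height", 96)),
        frame_width=int(cfg.get("frame_width", 128)),
        passband_fwhm=float(cfg.get("passband_fwhm", 10.0)),
    )


def _fluorophore_from_config(cfg: dict | None) -> Fluorophore:
    from .phantom import RIBOFLAVIN_LIKE

    if not cfg:
        return RIBOFLAVIN_LIKE
    return Fluorophore(
        name=cfg.get("name", "custom"),
        excitation_peak=float(cfg["excitation_peak"]),
        excitation_width=float(cfg["excitation_width"]),
        emission_peak=float(cfg["emission_peak"]),
        emission_width=float(cfg["emission_width"]),
        quantum_scale=float(cfg.get("quantum_scale", 1.0)),
    )


def scene_from_config(cfg: dict | None, seed: int | None = None) -> SceneSpec:
    cfg = dict(cfg or {})
    stains = tuple(
        StainRegion(
            shape=s.get("shape", "rectangle"),
            center=tuple(map(float, s["center_mm"])),
            extent=tuple(map(float, s["extent_mm"])),
            fluorophore=_fluorophore_from_config(s.get("fluorophore")),
            concentration=float(s.get("concentration", 1.0)),
        )
        for s in cfg.get("stains", [])
    )
    return SceneSpec(
        pixel_scale=float(cfg.get("pixel_scale_mm", 0.05)),
        background_reflectance=float(cfg.get("background_reflectance", 0.2)),
        stains=stains,
        noise_sd=float(cfg.get("noise_sd", 0.02)),
        seed=int(cfg["seed"] if seed is None and "seed" in cfg else (seed if seed is not None else 0)),
    )


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; loaded from a single YAML file.

    All randomness fans out from ``seed`` by fixed per-stage offsets, so a
    config plus a seed fully determines every artifact.
    """

    out_dir: Path
    seed: int = 0
    scene: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)  # threshold, light, filter_nm
    clustering: dict = field(default_factory=dict)  # k, restarts
    tiling: dict = field(default_factory=dict)  # tile_size, regularization, coverage
    hygiene_csv: Path | None = None
    log_level: str = "INFO"

    @property
    def threshold(self) -> float:
        return float(self.detection.get("threshold", 0.35))

    @property
    def detection_channel(self) -> tuple[str, float]:
        return (self.detection.get("light", "green"), float(self.detection.get("filter_nm", 500.0)))


def load_run_config(path: str | Path, seed: int | None = None, out_dir: str | None = None) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"run config {path} must be a mapping")
    hygiene = raw.get("hygiene_csv")
    hygiene_path = None
    if hygiene:
        hygiene_path = Path(hygiene)
        if not hygiene_path.is_absolute():
            hygiene_path = path.parent / hygiene_path
        if not hygiene_path.exists():
            raise ParameterError(f"hygiene samples CSV not found: {hygiene_path}")
    return RunConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "stainscan_run")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        scene=raw.get("scene", {}) or {},
        protocol=raw.get("protocol", {}) or {},
        detection=raw.get("detection", {}) or {},
        clustering=raw.get("clustering", {}) or {},
        tiling=raw.get("tiling", {}) or {},
        hygiene_csv=hygiene_path,
        log_level=str(raw.get("log_level", "INFO")),
    )
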