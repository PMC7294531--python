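"""One-command orchestration: phantom/scan -> segmentation -> hollowing -> meshing.

A single declarative configuration (YAML or JSON) carries every constant of
the fabrication workflow — the 80 HU assumed tissue level, the histogram
region, the hollowing mode and ports, the 128 iso-level — and a single seed
drives all randomness, so a run is reproducible bit-for-bit.  Each stage can
also be run on its own with intermediate MetaImage files; staged execution
equals the single-shot pipeline exactly because the intermediates are
lossless.  Logging goes to stderr, artifacts and a machine-readable JSON run
report to the output directory; nothing touches the network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import hollowing as hol
from . import meshing as msh
from . import phantom as ph
from . import segmentation as seg
from . import volume_io as vio
from .grid import BinaryMask, ImageVolume

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]

logger = logging.getLogger("vesselforge")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name for context."""


@dataclass
class PipelineConfig:
    """Declarative description of a full fabrication run.

    Exactly one of ``input_path`` (a scan readable by
    :func:`vesselforge.volume_io.read_volume`) or ``phantom_preset`` (one of
    the four named synthetic cases) must be given.  Sub-configurations left
    at ``None`` while a preset is active are filled with preset-derived
    defaults (histogram ROI over the sac, seed point on the centerline,
    ports at the vessel ends).
    """

    input_path: str | None = None
    phantom_preset: str | None = None
    output_dir: str = "vesselforge_out"
    seed: int = 0
    log_level: str = "INFO"
    segmentation: seg.SegmentationConfig = field(default_factory=seg.SegmentationConfig)
    hollowing: hol.HollowConfig | None = None
    meshing: msh.MeshConfig = field(default_factory=msh.MeshConfig)

    def __post_init__(self):
        if (self.input_path is None) == (self.phantom_preset is None):
            raise ValueError(
                "exactly one of input_path / phantom_preset must be given"
            )
        if self.phantom_preset is not None and self.phantom_preset not in ph.PRESET_NAMES:
            raise ValueError(
                f"unknown phantom preset {self.phantom_preset!r}; "
                f"choose from {ph.PRESET_NAMES}"
            )


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    peak_hu: float
    threshold_hu: float
    background_hu: float
    lumen_voxel_count: int
    lumen_volume_mm3: float
    mode: str
    mesh_report: msh.MeshReport
    max_diameter_mm: float
    config_sha256: str
    input_sha256: str
    timings_s: dict
    artifacts: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mesh_report"] = self.mesh_report.to_dict()
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Configuration loading and preset defaults
# ---------------------------------------------------------------------------

def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    seg_raw = dict(raw.get("segmentation") or {})
    for key in ("seed_point", "roi_center_mm"):
        if seg_raw.get(key) is not None:
            seg_raw[key] = tuple(seg_raw[key])
    if seg_raw.get("crop_box") is not None:
        seg_raw["crop_box"] = tuple(tuple(r) for r in seg_raw["crop_box"])
    hol_raw = raw.get("hollowing")
    hol_cfg = None
    if hol_raw is not None:
        hol_raw = dict(hol_raw)
        if "ports" in hol_raw:
            hol_raw["ports"] = tuple(
                hol.Port(**p) if isinstance(p, dict) else p for p in hol_raw["ports"]
            )
        hol_cfg = hol.HollowConfig(**hol_raw)
    return PipelineConfig(
        input_path=raw.get("input"),
        phantom_preset=raw.get("preset"),
        output_dir=str(raw.get("output_dir", "vesselforge_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        segmentation=seg.SegmentationConfig(**seg_raw),
        hollowing=hol_cfg,
        meshing=msh.MeshConfig(**dict(raw.get("meshing") or {})),
    )


def _canonical_config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(
        {
            "input_path": cfg.input_path,
            "phantom_preset": cfg.phantom_preset,
            "seed": cfg.seed,
            "segmentation": asdict(cfg.segmentation),
            "hollowing": asdict(cfg.hollowing) if cfg.hollowing else None,
            "meshing": asdict(cfg.meshing),
        },
        sort_keys=True,
        default=default,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def resolve_preset_defaults(cfg: PipelineConfig) -> PipelineConfig:
    """Fill preset-derived defaults (ROI, seed point, ports) into ``cfg``."""
    if cfg.phantom_preset is None:
        if cfg.hollowing is None:
            raise ValueError(
                "hollowing configuration (incl. ports) is required for "
                "non-preset inputs"
            )
        if cfg.segmentation.seed_point is None:
            raise ValueError("segmentation.seed_point is required for scan inputs")
        return cfg
    spec = ph.preset_spec(cfg.phantom_preset, seed=cfg.seed)
    s = cfg.segmentation
    changed = {}
    if s.roi_center_mm is None:
        changed["roi_center_mm"] = spec.aneurysm_center
    if s.roi_radius_mm is None:
        changed["roi_radius_mm"] = 0.4 * spec.aneurysm_diameter_mm
    if s.seed_point is None:
        changed["seed_point"] = tuple(
            int(round(spec.aneurysm_center[a] / spec.spacing[a])) for a in range(3)
        )
    if changed:
        s = replace(s, **changed)
    h = cfg.hollowing
    if h is None:
        # ports at both vessel ends, seeded a couple of voxels inside the
        # flat-capped tube so the seed voxel is safely within the lumen
        pts = np.asarray(spec.centerline)
        nudge = 2.0 * max(spec.spacing)
        ends = []
        for p, neighbour in ((pts[0], pts[1]), (pts[-1], pts[-2])):
            u = (neighbour - p) / np.linalg.norm(neighbour - p)
            ends.append(p + u * nudge)
        ports = tuple(
            hol.Port(
                seed=tuple(int(round(p[a] / spec.spacing[a])) for a in range(3)),
                direction=d,
            )
            for p, d in zip(ends, ("-x", "+x"))
        )
        h = hol.HollowConfig(ports=ports)
    return replace(cfg, segmentation=s, hollowing=h)


def mask_from_volume(vol: ImageVolume) -> BinaryMask:
    """Reinterpret a saved {0,255} volume as a binary mask."""
    return BinaryMask(data=vol.data, spacing=vol.spacing, origin=vol.origin)


def _mask_as_volume(mask: BinaryMask) -> ImageVolume:
    return ImageVolume(data=mask.data, spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# Stage functions (shared by the single-shot pipeline and the CLI stages)
# ---------------------------------------------------------------------------

def stage_acquire(cfg: PipelineConfig) -> tuple[ImageVolume, ph.PhantomGroundTruth | None]:
    if cfg.phantom_preset is not None:
        spec = ph.preset_spec(cfg.phantom_preset, seed=cfg.seed)
        vol, truth = ph.generate_phantom(spec)
        return vol, truth
    vol = vio.read_volume(cfg.input_path)
    return vol, None


def stage_segment(
    vol: ImageVolume, cfg: seg.SegmentationConfig
) -> tuple[BinaryMask, float, float]:
    """Histogram -> peak -> threshold -> binarize -> component -> crop."""
    roi = None
    if cfg.roi_center_mm is not None and cfg.roi_radius_mm is not None:
        roi = seg.sphere_roi(vol, cfg.roi_center_mm, cfg.roi_radius_mm)
    hist = seg.compute_histogram(vol, roi=roi, bin_width_hu=cfg.bin_width_hu)
    peak = seg.histogram_peak(hist)
    threshold = seg.threshold_from_peak(peak, cfg.background_hu)
    mask = seg.apply_threshold(vol, threshold)
    if cfg.seed_point is not None:
        mask = seg.select_component(mask, cfg.seed_point)
    if cfg.crop_box is not None:
        mask = seg.crop_box(mask, cfg.crop_box)
    return mask, peak, threshold


def stage_hollow(lumen: BinaryMask, cfg: hol.HollowConfig) -> BinaryMask:
    if cfg.mode == "block_complement":
        solid = hol.make_block_complement(lumen, cfg)
        lumen_conf = hol.conform_mask(lumen, solid)
        offset = np.round(
            (np.asarray(lumen.origin) - np.asarray(solid.origin))
            / np.asarray(lumen.spacing)
        ).astype(int)
        ports = tuple(
            hol.Port(seed=tuple(np.asarray(p.seed) + offset), direction=p.direction)
            for p in cfg.ports
        )
        shifted = hol.HollowConfig(
            mode=cfg.mode,
            block_margin_mm=cfg.block_margin_mm,
            wall_thickness_mm=cfg.wall_thickness_mm,
            ports=ports,
        )
        return hol.open_ports(solid, lumen_conf, shifted)
    solid = hol.make_shell(lumen, cfg)
    return hol.open_ports(solid, lumen, cfg)


def stage_mesh(model: BinaryMask, cfg: msh.MeshConfig):
    mesh = msh.extract_surface(model, cfg)
    report = msh.validate_mesh(mesh)
    diameter, _ = msh.mesh_summary(mesh)
    return mesh, report, diameter


# ---------------------------------------------------------------------------
# Single-shot pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run phantom/scan -> segmentation -> hollowing -> meshing end to end.

    Writes ``phantom.mha`` (presets only), ``lumen_mask.mha``,
    ``hollow_mask.mha``, ``model.stl`` and ``report.json`` into
    ``cfg.output_dir`` and returns the :class:`RunReport`.
    """
    cfg = resolve_preset_defaults(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 4)
        return result

    logger.info("acquiring input (%s)", cfg.phantom_preset or cfg.input_path)
    vol, truth = timed("acquire", stage_acquire, cfg)
    if truth is not None:
        vio.write_volume(vol, out / "phantom.mha")
        vio.write_volume(_mask_as_volume(truth.lumen_mask), out / "ground_truth_lumen.mha")
        artifacts["phantom"] = str(out / "phantom.mha")
        artifacts["ground_truth_lumen"] = str(out / "ground_truth_lumen.mha")
        input_hash = hashlib.sha256(np.ascontiguousarray(vol.data).tobytes()).hexdigest()
    else:
        input_hash = hashlib.sha256(np.ascontiguousarray(vol.data).tobytes()).hexdigest()

    logger.info("segmenting lumen")
    lumen, peak, threshold = timed("segment", stage_segment, vol, cfg.segmentation)
    logger.info("histogram peak %.1f HU -> threshold %.1f HU", peak, threshold)
    vio.write_volume(_mask_as_volume(lumen), out / "lumen_mask.mha")
    artifacts["lumen_mask"] = str(out / "lumen_mask.mha")

    logger.info("hollowing (%s)", cfg.hollowing.mode)
    hollow_mask = timed("hollow", stage_hollow, lumen, cfg.hollowing)
    vio.write_volume(_mask_as_volume(hollow_mask), out / "hollow_mask.mha")
    artifacts["hollow_mask"] = str(out / "hollow_mask.mha")

    logger.info("meshing at iso-level %.0f", cfg.meshing.iso_level)
    mesh, mesh_report, diameter = timed("mesh", stage_mesh, hollow_mask, cfg.meshing)
    vio.write_stl(mesh, out / "model.stl", dialect="binary")
    artifacts["model_stl"] = str(out / "model.stl")

    report = RunReport(
        peak_hu=peak,
        threshold_hu=threshold,
        background_hu=cfg.segmentation.background_hu,
        lumen_voxel_count=lumen.count(),
        lumen_volume_mm3=lumen.volume_mm3(),
        mode=cfg.hollowing.mode,
        mesh_report=mesh_report,
        max_diameter_mm=diameter,
        config_sha256=_canonical_config_hash(cfg),
        input_sha256=input_hash,
        timings_s=timings,
        artifacts=artifacts,
    )
    report.write_json(out / "report.json")
    assert report.threshold_hu == (report.peak_hu + report.background_hu) / 2.0
    return report
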