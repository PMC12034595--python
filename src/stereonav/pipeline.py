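"""End-to-end pipeline driver: images -> disparity -> cloud -> registration -> overlay.

The driver consumes a single YAML config (every parameter needed to
reproduce a run is either in the config or derived from its seed) and
writes all artifacts plus a structured JSON log into the output
directory.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .cloud import cloud_from_disparity, pick_landmark_3d, remove_outliers
from .errors import ConfigError, StereoNavError
from .io import (
    read_landmarks,
    read_mesh,
    read_rig,
    write_cloud_ply,
    write_disparity,
    write_transform,
)
from .overlay import OverlayStyle, render_overlay
from .preprocess import StereoFrame, deinterlace_vats, rectify_pair
from .register import LandmarkSet, fit_rigid
from .stereo import DisparityParams, compute_disparity

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run (paths + parameters)."""

    calibration: str
    output_dir: str
    left_image: Optional[str] = None
    right_image: Optional[str] = None
    interlaced_image: Optional[str] = None
    parity: str = "even-left"
    disparity: dict = field(default_factory=dict)
    outlier_removal: Optional[dict] = None
    preop_landmarks: Optional[str] = None
    intraop_landmarks: Optional[str] = None
    intraop_pixels: Optional[str] = None
    landmark_convention: str = "RAS"
    pick_window: int = 5
    meshes: list = field(default_factory=list)
    overlay_style: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.calibration:
            raise ConfigError("config is missing the calibration path")
        required = [self.calibration]
        if self.interlaced_image:
            required.append(self.interlaced_image)
        elif self.left_image and self.right_image:
            required += [self.left_image, self.right_image]
        else:
            raise ConfigError("config needs either interlaced_image or left_image+right_image")
        for opt in (self.preop_landmarks, self.intraop_landmarks, self.intraop_pixels,
                    self.overlay_style, *[m["path"] if isinstance(m, dict) else m for m in self.meshes]):
            if opt:
                required.append(opt)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if self.pick_window < 1 or self.pick_window % 2 == 0:
            raise ConfigError("pick_window must be a positive odd integer")


def _style_from_yaml(path) -> OverlayStyle:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("visible", "opacity", "behind_surface_multiplier", "show_labels", "zoom"):
        if key in data:
            kwargs[key] = data[key]
    if "crop_center" in data:
        kwargs["crop_center"] = np.asarray(data["crop_center"], dtype=float)
        kwargs["crop_radius_mm"] = float(data["crop_radius_mm"])
    return OverlayStyle(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute preprocess -> disparity -> cloud -> register -> overlay.

    Returns a dict of artifact paths and headline numbers; also writes a
    ``run_log.json`` recording the config hash, seed and package version.
    """
    import imageio.v3 as iio

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "setup"
    try:
        rig = read_rig(config.calibration)

        stage = "preprocess"
        if config.interlaced_image:
            raw = iio.imread(config.interlaced_image)
            left, right = deinterlace_vats(raw, parity=config.parity)
        else:
            left = iio.imread(config.left_image)
            right = iio.imread(config.right_image)
        frame = rectify_pair(StereoFrame(left, right), rig)

        stage = "disparity"
        params = DisparityParams(**config.disparity)
        dmap = compute_disparity(frame, params)
        write_disparity(dmap, out / "disparity.tif")
        artifacts["disparity"] = str(out / "disparity.tif")

        stage = "cloud"
        cloud = cloud_from_disparity(dmap, rig.q_matrix, frame.left_image)
        if config.outlier_removal is not None:
            cloud = remove_outliers(cloud, **config.outlier_removal)
        write_cloud_ply(cloud, out / "cloud.ply")
        artifacts["cloud"] = str(out / "cloud.ply")
        artifacts["n_points"] = len(cloud)

        transform = None
        if config.preop_landmarks and (config.intraop_landmarks or config.intraop_pixels):
            stage = "register"
            preop = read_landmarks(config.preop_landmarks, config.landmark_convention, frame="preop")
            if config.intraop_pixels:
                picks = json.loads(Path(config.intraop_pixels).read_text())
                names, pts = [], []
                for name in preop.names:  # correspondence strictly by name
                    if name not in picks:
                        continue
                    px = picks[name]
                    pts.append(pick_landmark_3d(cloud, (px[0], px[1]), config.pick_window))
                    names.append(name)
                intraop = LandmarkSet(np.asarray(pts).reshape(-1, 3), names, frame="intraop")
                preop = preop.subset(names)
            else:
                intraop = read_landmarks(
                    config.intraop_landmarks, config.landmark_convention, frame="intraop"
                )
            result = fit_rigid(preop, intraop)
            transform = result.transform
            write_transform(transform, out / "transform.yaml", rmsd_mm=result.rmsd_mm)
            report = {
                "rmsd_mm": result.rmsd_mm,
                "n_landmarks": result.n_landmarks,
                "residuals_mm": result.residuals_mm.tolist(),
                "landmark_names": list(intraop.names),
            }
            (out / "registration_report.json").write_text(json.dumps(report, indent=1))
            artifacts["transform"] = str(out / "transform.yaml")
            artifacts["rmsd_mm"] = result.rmsd_mm

        if config.meshes and transform is not None:
            stage = "overlay"
            meshes = []
            for entry in config.meshes:
                if isinstance(entry, dict):
                    meshes.append(read_mesh(entry["path"], entry.get("label", "artery")))
                else:
                    meshes.append(read_mesh(entry))
            style = _style_from_yaml(config.overlay_style) if config.overlay_style else OverlayStyle()
            overlay = render_overlay(
                frame.left_image, cloud, meshes, transform, rig.rectified_left_intrinsics(), style
            )
            iio.imwrite(out / "overlay.png", overlay)
            artifacts["overlay"] = str(out / "overlay.png")
    except StereoNavError as exc:
        log = {"status": "error", "stage": stage, "error": str(exc)}
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
        raise StereoNavError(f"pipeline failed in stage '{stage}': {exc}") from exc

    cfg_repr = json.dumps(config.__dict__, sort_keys=True, default=str)
    log = {
        "status": "ok",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "config": json.loads(cfg_repr),
        "artifacts": {k: v for k, v in artifacts.items() if isinstance(v, str)},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    artifacts["log"] = str(out / "run_log.json")
    return artifacts
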