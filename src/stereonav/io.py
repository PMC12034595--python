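"""File formats: meshes, fiducials, calibration YAML, disparity, clouds.

Landmark files use the Slicer markups dialects (comment-headed fiducial
CSV and the JSON markups schema).  Slicer works in RAS ("right, anterior,
superior") while DICOM/ITK pipelines use LPS; converting between the two
negates x and y.  Calibration YAML stores the assembled Q matrix
redundantly and revalidates it against the rectified parameters on load,
so a hand-edited file cannot silently desynchronize.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path

import numpy as np
import tifffile
import trimesh
import yaml

from .camera import CameraIntrinsics, StereoRig, assemble_q
from .cloud import PointCloud
from .errors import LandmarkFileError, MeshError, ConfigError
from .overlay import SurfaceMesh
from .register import LandmarkSet, RigidTransform
from .stereo import DisparityMap, DisparityParams

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_rig",
    "write_rig",
    "read_transform",
    "write_transform",
    "write_disparity",
    "read_disparity",
    "write_cloud_ply",
    "read_cloud_ply",
]

_MESH_EXTENSIONS = {".ply", ".obj", ".stl"}


def read_mesh(path, label: str = "artery") -> SurfaceMesh:
    """Load a PLY/OBJ/STL triangle mesh (units mm, indices 0-based)."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise MeshError(f"unsupported mesh extension {path.suffix!r} (use PLY, OBJ or STL)")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise MeshError(f"failed to parse {path.name}: {exc}") from exc
    if not hasattr(tm, "faces") or len(getattr(tm, "faces", [])) == 0:
        raise MeshError(f"{path.name} contains no triangle faces")
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), label=label)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise MeshError(f"unsupported mesh extension {path.suffix!r} (use PLY, OBJ or STL)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


# --------------------------------------------------------------------------
# fiducial landmarks (Slicer markups dialects)
# --------------------------------------------------------------------------


def _flip_ras_lps(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


def read_landmarks(path, convention: str = "RAS", frame: str = "preop") -> LandmarkSet:
    """Read a fiducial CSV or markups JSON file into the given convention.

    ``convention`` is the coordinate system you want the points in (RAS or
    LPS); if the file declares the other one, x and y are negated.
    """
    path = Path(path)
    convention = convention.upper()
    if convention not in ("RAS", "LPS"):
        raise ValueError("convention must be 'RAS' or 'LPS'")
    if path.suffix.lower() == ".json":
        names, pts, file_conv = _read_markups_json(path)
    else:
        names, pts, file_conv = _read_fiducial_csv(path)
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if file_conv != convention:
        pts = _flip_ras_lps(pts)
    if len(set(names)) != len(names):
        raise LandmarkFileError(f"duplicate landmark names in {path.name}")
    return LandmarkSet(pts, list(names), frame=frame)


def _read_fiducial_csv(path: Path):
    file_conv = "RAS"
    rows = []
    header = None
    try:
        text = path.read_text()
    except OSError as exc:
        raise LandmarkFileError(str(exc)) from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            low = line.lower().replace(" ", "")
            if "coordinatesystem" in low:
                val = low.split("=")[-1].strip()
                file_conv = "LPS" if val in ("lps", "1") else "RAS"
            if "columns=" in low:
                header = low.split("=")[-1].split(",")
            continue
        rows.append((lineno, line))
    if header is None:
        header = ["id", "x", "y", "z", "ow", "ox", "oy", "oz", "vis", "sel", "lock", "label", "desc", "associatednodeid"]
    for col in ("x", "y", "z"):
        if col not in header:
            raise LandmarkFileError(f"{path.name}: missing required column {col!r}")
    ix, iy, iz = header.index("x"), header.index("y"), header.index("z")
    ilabel = header.index("label") if "label" in header else (header.index("id") if "id" in header else None)
    names, pts = [], []
    for lineno, line in rows:
        fields = next(csv.reader(_io.StringIO(line)))
        try:
            pts.append([float(fields[ix]), float(fields[iy]), float(fields[iz])])
        except (ValueError, IndexError) as exc:
            raise LandmarkFileError(f"{path.name}:{lineno}: cannot parse coordinates") from exc
        if ilabel is not None and ilabel < len(fields) and fields[ilabel]:
            names.append(fields[ilabel])
        else:
            names.append(f"F-{len(names) + 1}")
    if not pts:
        raise LandmarkFileError(f"{path.name}: no fiducial rows found")
    return names, pts, file_conv


def _read_markups_json(path: Path):
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LandmarkFileError(f"failed to parse {path.name}: {exc}") from exc
    try:
        markup = data["markups"][0]
        points = markup["controlPoints"]
    except (KeyError, IndexError, TypeError) as exc:
        raise LandmarkFileError(f"{path.name}: not a markups JSON file") from exc
    file_conv = str(markup.get("coordinateSystem", "LPS")).upper()
    if file_conv not in ("RAS", "LPS"):
        raise LandmarkFileError(f"{path.name}: unknown coordinate system {file_conv!r}")
    names, pts = [], []
    for i, cp in enumerate(points):
        if "position" not in cp:
            raise LandmarkFileError(f"{path.name}: control point {i} lacks a position")
        pts.append([float(v) for v in cp["position"]])
        names.append(cp.get("label") or f"F-{i + 1}")
    if not pts:
        raise LandmarkFileError(f"{path.name}: no control points")
    return names, pts, file_conv


def write_landmarks(landmarks: LandmarkSet, path, convention: str = "RAS") -> None:
    """Write fiducials as Slicer CSV (.fcsv/.csv) or markups JSON (.json)."""
    path = Path(path)
    convention = convention.upper()
    pts = landmarks.points
    if path.suffix.lower() == ".json":
        payload = {
            "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json",
            "markups": [
                {
                    "type": "Fiducial",
                    "coordinateSystem": convention,
                    "coordinateUnits": "mm",
                    "controlPoints": [
                        {"id": str(i + 1), "label": name, "position": list(map(float, p))}
                        for i, (name, p) in enumerate(zip(landmarks.names, pts))
                    ],
                }
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = [
        "# Markups fiducial file version = 4.11",
        f"# CoordinateSystem = {convention}",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (name, p) in enumerate(zip(landmarks.names, pts)):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},0,0,0,1,1,1,0,{name},,"
        )
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# calibration YAML
# --------------------------------------------------------------------------


def _intr_to_dict(intr: CameraIntrinsics) -> dict:
    return {
        "focal_length_px": float(intr.focal_length_px),
        "principal_point_px": [float(v) for v in intr.principal_point_px],
        "image_size": [int(v) for v in intr.image_size],
        "distortion": [float(v) for v in intr.distortion],
    }


def _intr_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        d["focal_length_px"], tuple(d["principal_point_px"]), tuple(d["image_size"]), d["distortion"]
    )


def write_rig(rig: StereoRig, path) -> None:
    """Serialize a rig to YAML, including the (redundant) Q matrix."""
    data = {
        "left": _intr_to_dict(rig.left),
        "right": _intr_to_dict(rig.right),
        "rotation": rig.rotation.tolist(),
        "translation": rig.translation.tolist(),
        "rectified": {
            "focal_px": float(rig.rectified_focal),
            "left_principal": [float(v) for v in rig.rectified_left_principal],
            "right_principal_x": float(rig.rectified_right_principal_x),
            "baseline_tx_mm": float(rig.baseline_tx_mm),
        },
        "q_matrix": rig.q_matrix.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_rig(path) -> StereoRig:
    """Load a rig YAML; the stored Q is revalidated against the rectified
    parameters and a mismatch is a hard error."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"failed to read rig file: {exc}") from exc
    rect = data["rectified"]
    rig = StereoRig(
        left=_intr_from_dict(data["left"]),
        right=_intr_from_dict(data["right"]),
        rotation=np.asarray(data["rotation"], dtype=float),
        translation=np.asarray(data["translation"], dtype=float),
        rectified_focal=rect["focal_px"],
        rectified_left_principal=tuple(rect["left_principal"]),
        rectified_right_principal_x=rect["right_principal_x"],
        baseline_tx_mm=rect["baseline_tx_mm"],
    )
    stored_q = np.asarray(data["q_matrix"], dtype=float)
    expected = assemble_q(
        rect["focal_px"],
        rect["left_principal"][0],
        rect["left_principal"][1],
        rect["right_principal_x"],
        rect["baseline_tx_mm"],
    )
    if not np.allclose(stored_q, expected, rtol=0, atol=1e-9):
        raise ConfigError("stored Q matrix is inconsistent with the rectified parameters")
    return rig


def write_transform(transform: RigidTransform, path, *, rmsd_mm: float | None = None) -> None:
    data = {"matrix": transform.matrix().tolist()}
    if rmsd_mm is not None:
        data["rmsd_mm"] = float(rmsd_mm)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_transform(path) -> RigidTransform:
    data = yaml.safe_load(Path(path).read_text())
    return RigidTransform.from_matrix(np.asarray(data["matrix"], dtype=float))


# --------------------------------------------------------------------------
# disparity maps and point clouds
# --------------------------------------------------------------------------

_PNG_SCALE = 16  # fixed point: 1/16 px
_PNG_SENTINEL = 0xFFFF  # -1 as two's-complement int16


def write_disparity(dmap: DisparityMap, path) -> None:
    """16-bit fixed-point PNG (.png, 1/16 px, 0xFFFF sentinel) or float TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), dmap.disparity.astype(np.float32))
        return
    if path.suffix.lower() != ".png":
        raise ValueError("disparity export supports .png and .tif/.tiff")
    import imageio.v3 as iio

    fixed = np.round(np.nan_to_num(dmap.disparity, nan=0.0) * _PNG_SCALE).astype(np.int64)
    fixed = np.clip(fixed, 0, _PNG_SENTINEL - 1).astype(np.uint16)
    fixed[~dmap.valid_mask] = _PNG_SENTINEL
    iio.imwrite(str(path), fixed)


def read_disparity(path, params: DisparityParams | None = None) -> DisparityMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        disp = tifffile.imread(str(path)).astype(np.float32)
        valid = np.isfinite(disp)
    else:
        import imageio.v3 as iio

        raw = iio.imread(str(path))
        valid = raw != _PNG_SENTINEL
        disp = np.where(valid, raw.astype(np.float32) / _PNG_SCALE, np.nan)
    return DisparityMap(disp, valid, params or DisparityParams())


def write_cloud_ply(cloud: PointCloud, path) -> None:
    """Binary little-endian PLY with per-vertex 8-bit color."""
    tm = trimesh.PointCloud(
        cloud.points, colors=np.column_stack([cloud.colors, np.full(len(cloud), 255, dtype=np.uint8)])
    )
    tm.export(str(path))


def read_cloud_ply(path) -> PointCloud:
    tm = trimesh.load(str(path), process=False)
    colors = np.asarray(tm.colors)[:, :3] if len(getattr(tm, "colors", [])) else None
    return PointCloud(np.asarray(tm.vertices, dtype=float), colors)
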