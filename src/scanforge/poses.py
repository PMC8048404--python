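"""Analytic camera-pose priors for a two-axis-gimbal scanner.

The scanner rotates the *specimen* on a gimbal (tilt about X, full rotation
about Y) while the camera stays fixed on its rail.  Photogrammetry software
instead assumes a fixed scene and a moving camera, so each specimen rotation
is inverted onto the camera (the equivalent-camera-motion model): for gimbal
angles (x, y) the virtual camera centre is

    c = R_y(-y) . R_x(-x) . (0, 0, r)

with r the camera-to-centre working distance, and the camera orientation is
the look-at rotation from c toward the dome centre (the world origin).

World frame: right-handed, +Y up (the gimbal's vertical axis), +Z from dome
centre toward the camera home position.  The camera looks along its local
-Z.  Yaw (Y) is applied after tilt (X), matching the physical nesting of the
stages.  The resulting poses are serialised as a .sfm scene file (JSON
dialect used by AliceVision/Meshroom) that seeds the SfM solver; they are
rig-model priors, not metrically solved poses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

#: tilt span beyond which the dome no longer backs every view
MAX_TILT_SPAN_DEG = 100.0


@dataclass
class CameraIntrinsics:
    """Shared intrinsics of every view in a scan."""

    make: str = ""
    model: str = ""
    serial: str = ""
    focal_length_mm: float = 0.0
    focal_length_35mm: float = 0.0
    sensor_width_mm: float = 0.0
    image_width_px: int = 0
    image_height_px: int = 0


@dataclass
class CameraPose:
    """Camera-to-world rotation and camera centre (mm, origin at dome centre)."""

    rotation: np.ndarray
    centre: np.ndarray


@dataclass
class ScanConfig:
    """Angle grid and camera geometry of one scan.

    ``image_names`` matches the pose grid in row-major order (x outer,
    y inner).  The X (tilt) span is limited to ~100 degrees on the physical
    rig; wider spans are accepted with a warning.
    """

    x_angles_deg: list[float]
    y_angles_deg: list[float]
    radius: float
    intrinsics: CameraIntrinsics
    image_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.x_angles_deg or not self.y_angles_deg:
            raise InvalidInputError("angle lists must be non-empty")
        if self.radius <= 0:
            raise InvalidInputError("radius must be positive")
        span = max(self.x_angles_deg) - min(self.x_angles_deg)
        if span > MAX_TILT_SPAN_DEG:
            import warnings

            warnings.warn(
                f"X-tilt span {span:.1f} deg exceeds the "
                f"{MAX_TILT_SPAN_DEG:.0f} deg dome coverage", UserWarning
            )


@dataclass
class SfmScene:
    """Serializable SfM prior: views, one shared intrinsics, per-view poses."""

    views: list[dict]
    intrinsics: CameraIntrinsics
    poses: list[CameraPose]


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def camera_pose(x_deg: float, y_deg: float, radius: float) -> CameraPose:
    """Equivalent-camera pose for gimbal angles (x tilt, y rotation).

    The centre lies on the sphere of radius ``radius`` and the rotation is
    the look-at matrix toward the origin with world +Y as the up reference
    (world +X when the viewing axis is within 1e-6 of +/-Y, a pose the
    physical gimbal cannot reach).
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    centre = _rot_y(-y_deg) @ _rot_x(-x_deg) @ np.array([0.0, 0.0, radius])
    forward = -centre / np.linalg.norm(centre)  # unit vector centre -> origin
    z_cam = -forward  # camera looks along local -Z
    up = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(z_cam, up)) > 1.0 - 1e-6:
        up = np.array([1.0, 0.0, 0.0])
    x_cam = np.cross(up, z_cam)
    x_cam /= np.linalg.norm(x_cam)
    y_cam = np.cross(z_cam, x_cam)
    rotation = np.column_stack([x_cam, y_cam, z_cam])
    return CameraPose(rotation=rotation, centre=centre)


def pose_grid(config: ScanConfig) -> SfmScene:
    """One pose per (x, y) grid point, row-major (x outer, y inner)."""
    n = len(config.x_angles_deg) * len(config.y_angles_deg)
    names = config.image_names
    if names and len(names) != n:
        raise InvalidInputError(
            f"{len(names)} image names for {n} grid poses"
        )
    if not names:
        names = [
            f"x{int(round(x)):+04d}_y{int(round(y)):03d}.png"
            for x in config.x_angles_deg
            for y in config.y_angles_deg
        ]
    poses, views = [], []
    idx = 0
    for x in config.x_angles_deg:
        for y in config.y_angles_deg:
            poses.append(camera_pose(x, y, config.radius))
            views.append(
                {
                    "view_id": idx,
                    "pose_id": idx,
                    "intrinsic_id": 0,
                    "path": names[idx],
                    "x_deg": float(x),
                    "y_deg": float(y),
                }
            )
            idx += 1
    return SfmScene(views=views, intrinsics=config.intrinsics, poses=poses)


def _fmt(v: float) -> str:
    return f"{v:.15e}"


def write_sfm(scene: SfmScene, path: str | Path) -> None:
    """Serialise the scene as an AliceVision-dialect .sfm JSON document.

    Rotations are written as 9 row-major numbers, centres as 3 numbers, all
    with fixed float formatting and sorted keys so identical scenes produce
    byte-identical files.
    """
    intr = scene.intrinsics
    doc = {
        "version": ["1", "0", "0"],
        "views": [
            {
                "viewId": str(v["view_id"]),
                "poseId": str(v["pose_id"]),
                "intrinsicId": str(v["intrinsic_id"]),
                "path": v["path"],
                "width": str(intr.image_width_px),
                "height": str(intr.image_height_px),
            }
            for v in scene.views
        ],
        "intrinsics": [
            {
                "intrinsicId": "0",
                "width": str(intr.image_width_px),
                "height": str(intr.image_height_px),
                "serialNumber": intr.serial,
                "type": "pinhole",
                "focalLength": _fmt(intr.focal_length_mm),
                "sensorWidth": _fmt(intr.sensor_width_mm),
            }
        ],
        "poses": [
            {
                "poseId": str(i),
                "pose": {
                    "transform": {
                        "rotation": [_fmt(x) for x in p.rotation.ravel()],
                        "center": [_fmt(x) for x in p.centre],
                    },
                    "locked": "0",
                },
            }
            for i, p in enumerate(scene.poses)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_sfm(path: str | Path) -> SfmScene:
    """Parse a .sfm file written by :func:`write_sfm`."""
    doc = json.loads(Path(path).read_text())
    intr_rec = doc["intrinsics"][0]
    intrinsics = CameraIntrinsics(
        serial=intr_rec.get("serialNumber", ""),
        focal_length_mm=float(intr_rec["focalLength"]),
        sensor_width_mm=float(intr_rec["sensorWidth"]),
        image_width_px=int(intr_rec["width"]),
        image_height_px=int(intr_rec["height"]),
    )
    poses = [
        CameraPose(
            rotation=np.array(
                [float(x) for x in rec["pose"]["transform"]["rotation"]]
            ).reshape(3, 3),
            centre=np.array(
                [float(x) for x in rec["pose"]["transform"]["center"]]
            ),
        )
        for rec in doc["poses"]
    ]
    views = [
        {
            "view_id": int(v["viewId"]),
            "pose_id": int(v["poseId"]),
            "intrinsic_id": int(v["intrinsicId"]),
            "path": v["path"],
        }
        for v in doc["views"]
    ]
    return SfmScene(views=views, intrinsics=intrinsics, poses=poses)
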