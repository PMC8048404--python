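"""EXIF metadata embedding for processed EDOF images.

SfM reconstruction needs setup-specific metadata — camera make/model (sensor
database lookup), a shared serial number (so intrinsics solved for one scene
apply to all), the lens focal length, its 35 mm-equivalent, and the physical
sensor width — embedded in every image.  Make/Model/serial/focal lengths map
to standard EXIF tags.  Sensor width has no standard EXIF tag of its own, so
it is stored losslessly as the focal-plane resolution pair
(FocalPlaneXResolution in pixels per centimetre, as an exact rational) and
reconstructed on read.  Pixel data is never touched: the image is re-encoded
losslessly with the new metadata.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from PIL import Image
from PIL.TiffImagePlugin import IFDRational

from .errors import ConfigurationError
from .poses import CameraIntrinsics

TAG_MAKE = 271
TAG_MODEL = 272
TAG_FOCAL_LENGTH = 37386
TAG_FOCAL_PLANE_X_RES = 41486
TAG_FOCAL_PLANE_UNIT = 41488  # 3 = centimetre
TAG_FOCAL_35MM = 41989
TAG_SERIAL = 42033

_REQUIRED = {
    "Make": "make",
    "Model": "model",
    "CameraSerialNumber": "serial",
    "FocalLength": "focal_length_mm",
    "FocalLengthIn35mmFormat": "focal_length_35mm",
    "SensorWidth": "sensor_width_mm",
}


def _sensor_width_fraction(sensor_width_mm: float) -> Fraction:
    # exact for sensor widths specified to <=1e-6 mm
    return Fraction(round(sensor_width_mm * 10**6), 10**6)


def write_exif(image_path: str | Path, intrinsics: CameraIntrinsics) -> None:
    """Embed the reconstruction metadata of ``intrinsics`` into an image file.

    All required fields must be present; a missing one raises a
    configuration error naming the field.  The image is rewritten in place
    with identical pixel data (PNG/TIFF are lossless).
    """
    for label, attr in _REQUIRED.items():
        value = getattr(intrinsics, attr)
        if value in ("", None) or (isinstance(value, (int, float)) and value <= 0):
            raise ConfigurationError(f"required metadata field {label} is missing")
    path = Path(image_path)
    if not path.exists():
        raise ConfigurationError(f"image not found: {path}")
    with Image.open(path) as im:
        im.load()
        exif = im.getexif()
        exif[TAG_MAKE] = intrinsics.make
        exif[TAG_MODEL] = intrinsics.model
        exif[TAG_SERIAL] = intrinsics.serial
        exif[TAG_FOCAL_LENGTH] = float(intrinsics.focal_length_mm)
        exif[TAG_FOCAL_35MM] = float(intrinsics.focal_length_35mm)
        width_px = im.size[0]
        per_cm = Fraction(width_px * 10) / _sensor_width_fraction(
            intrinsics.sensor_width_mm
        )
        exif[TAG_FOCAL_PLANE_X_RES] = IFDRational(
            per_cm.numerator, per_cm.denominator
        )
        exif[TAG_FOCAL_PLANE_UNIT] = 3
        im.save(path, exif=exif)


def read_exif(image_path: str | Path) -> CameraIntrinsics:
    """Read back the metadata written by :func:`write_exif`."""
    with Image.open(Path(image_path)) as im:
        exif = im.getexif()
        width_px, height_px = im.size
    res = exif.get(TAG_FOCAL_PLANE_X_RES)
    sensor_width = 0.0
    if res:
        per_cm = Fraction(res.numerator, res.denominator)
        sensor_width = float(Fraction(width_px * 10) / per_cm)
    return CameraIntrinsics(
        make=str(exif.get(TAG_MAKE, "")),
        model=str(exif.get(TAG_MODEL, "")),
        serial=str(exif.get(TAG_SERIAL, "")),
        focal_length_mm=float(exif.get(TAG_FOCAL_LENGTH, 0.0)),
        focal_length_35mm=float(exif.get(TAG_FOCAL_35MM, 0.0)),
        sensor_width_mm=sensor_width,
        image_width_px=width_px,
        image_height_px=height_px,
    )


def pixel_checksum(image_path: str | Path) -> str:
    """SHA-256 of the decoded pixel data (metadata excluded)."""
    import hashlib

    with Image.open(Path(image_path)) as im:
        arr = np.asarray(im)
    return hashlib.sha256(arr.tobytes()).hexdigest()
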