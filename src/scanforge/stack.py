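"""Focal-stack container and stack I/O.

A focal stack is the ordered set of images captured at one viewing
perspective while the camera advances along its rail; z index 0 is the most
distal focal plane (camera farthest from the specimen), which also has the
smallest magnification and therefore serves as the geometric reference for
alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError

#: filename convention for captured planes: x{+/-ddd}_y{ddd}_z{dd}.{tif,png}
STACK_FILENAME_RE = re.compile(
    r"x(?P<x>[+-]?\d+)_y(?P<y>\d+)_z(?P<z>\d+)\.(tif|tiff|png)$", re.IGNORECASE
)


@dataclass
class ImageStack:
    """Ordered single-perspective focal stack.

    Parameters
    ----------
    images:
        Pixel arrays, all sharing height, width, channel count and dtype.
        2-D arrays are greyscale, 3-D arrays are RGB.
    z_indices:
        Strictly increasing plane indices; 0 is the most distal plane.
    perspective_id:
        ``(x_angle_deg, y_angle_deg)`` of the gimbal for this stack.
    filenames:
        Optional provenance, parallel to ``images``.
    """

    images: list[np.ndarray]
    z_indices: list[int]
    perspective_id: tuple[float, float] = (0.0, 0.0)
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.z_indices):
            raise InvalidInputError("images and z_indices differ in length")
        if self.images:
            ref = self.images[0]
            for im in self.images:
                if im.shape != ref.shape or im.dtype != ref.dtype:
                    raise InvalidInputError(
                        "all stack images must share shape and dtype"
                    )
        z = list(self.z_indices)
        if any(b <= a for a, b in zip(z, z[1:])):
            raise InvalidInputError("z_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple:
        return self.images[0].shape if self.images else ()

    def subset(self, keep: Sequence[int]) -> "ImageStack":
        """Sub-stack of the positions in ``keep`` (z order preserved)."""
        keep = sorted(keep)
        return ImageStack(
            images=[self.images[i] for i in keep],
            z_indices=[self.z_indices[i] for i in keep],
            perspective_id=self.perspective_id,
            filenames=[self.filenames[i] for i in keep] if self.filenames else [],
        )


def load_stack(directory: str | Path, perspective_id=(0.0, 0.0)) -> ImageStack:
    """Read a focal stack from a directory of TIFF/PNG files.

    Files matching the ``x{ang}_y{ang}_z{idx}`` convention are ordered by
    their z index; any other TIFF/PNG files are ordered by filename and given
    sequential z indices.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".tif", ".tiff", ".png"}
        and ".gt." not in p.name  # ground-truth sidecars are not planes
    )
    if not paths:
        raise InvalidInputError(f"no TIFF/PNG images found in {directory}")
    z_of: dict[Path, int] = {}
    for p in paths:
        m = STACK_FILENAME_RE.search(p.name)
        if m:
            z_of[p] = int(m.group("z"))
    if len(z_of) == len(paths):
        paths = sorted(paths, key=lambda p: z_of[p])
        z_indices = [z_of[p] for p in paths]
    else:
        z_indices = list(range(len(paths)))
    images = [np.asarray(iio.imread(p)) for p in paths]
    return ImageStack(
        images=images,
        z_indices=z_indices,
        perspective_id=perspective_id,
        filenames=[p.name for p in paths],
    )
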