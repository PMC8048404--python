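"""Winner-takes-all fusion of an aligned focal stack into one EDOF image.

Each output pixel is copied verbatim from the focal plane with the highest
local sharpness at that position (a "hard mask" in exposure-fusion
terminology).  Selection is driven purely by local contrast — luminance and
saturation carry zero weight — which maximises detail and avoids the halos
produced by soft averaging across planes.  Colour is copied untouched from
the winning plane; only the selection map is computed on a grey projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, uniform_filter

from .errors import InvalidInputError
from .focus import LAPLACIAN_3X3
from .stack import ImageStack

#: default neighbourhood (pixels) for the local sharpness energy
DEFAULT_WINDOW = 7
#: window of the majority filter smoothing the plane-selection map
MAJORITY_WINDOW = 5


@dataclass
class EdofImage:
    """Blended all-in-focus image with provenance."""

    pixels: np.ndarray
    perspective_id: tuple[float, float] = (0.0, 0.0)
    provenance: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def grey_project(image: np.ndarray, mode: str = "average") -> np.ndarray:
    """Project an RGB image to a scalar intensity.

    ``average``
        Arithmetic mean of the three channels (the default projector).
    ``l_star``
        CIE 1976 L* lightness of the linearised sRGB input, rescaled to the
        input intensity range.  L* spaces out small contrast differences in
        highlights and shadows, which can suppress halos at plane seams.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError("grey_project expects a 3-channel RGB image")
    if mode == "average":
        return image.mean(axis=2)
    if mode == "l_star":
        if np.issubdtype(image.dtype, np.integer):
            full = float(np.iinfo(image.dtype).max)
        else:
            full = 1.0
        srgb = image.astype(np.float64) / full
        linear = np.where(
            srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4
        )
        # Rec.709 luminance of the linear channels
        y = linear @ np.array([0.2126, 0.7152, 0.0722])
        eps = (6.0 / 29.0) ** 3
        f = np.where(y > eps, np.cbrt(y), y / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
        l_star = 116.0 * f - 16.0
        return l_star * (full / 100.0)
    raise InvalidInputError(f"unknown grey projector {mode!r}")


def _to_grey(image: np.ndarray, projector: str) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.float64)
    return grey_project(image, projector)


def local_contrast_map(image: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-pixel sharpness energy: local variance of the Laplacian response.

    A sharp edge produces strong positive/negative Laplacian excursions
    within the window, hence high variance; smooth regions score near zero.
    ``window`` must be odd and >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidInputError("window must be an odd integer >= 3")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InvalidInputError("local_contrast_map expects a 2-D grey image")
    response = convolve(image, LAPLACIAN_3X3, mode="reflect")
    m1 = uniform_filter(response, size=window, mode="reflect")
    m2 = uniform_filter(response * response, size=window, mode="reflect")
    return np.maximum(m2 - m1 * m1, 0.0)


def _majority_filter(labels: np.ndarray, n_labels: int, window: int) -> np.ndarray:
    """Replace each label by the most frequent label in its window.

    Ties resolve to the lowest label, matching the distal-plane-wins rule.
    """
    votes = np.empty((n_labels,) + labels.shape)
    for k in range(n_labels):
        votes[k] = uniform_filter(
            (labels == k).astype(np.float64), size=window, mode="reflect"
        )
    return votes.argmax(axis=0)


def blend_hard_mask(
    stack: ImageStack,
    window: int = DEFAULT_WINDOW,
    grey_projector: str = "average",
) -> tuple[EdofImage, np.ndarray]:
    """Fuse an aligned stack; returns the EDOF image and its index map.

    Per pixel, the plane with the maximum local contrast wins and its pixel
    is copied bit-identically; the index map records the winning z index for
    every pixel.  Ties break toward the lowest z index (most distal plane).
    The raw argmax map is smoothed with a small majority filter to suppress
    isolated plane switching; the copy happens after smoothing, so the
    hard-mask property (every output pixel exists verbatim in its source
    plane) always holds.
    """
    if len(stack) == 0:
        raise InvalidInputError("cannot blend an empty stack")
    z = np.asarray(stack.z_indices)
    if len(stack) == 1:
        edof = EdofImage(
            pixels=stack.images[0].copy(),
            perspective_id=stack.perspective_id,
            provenance=list(stack.filenames),
        )
        return edof, np.full(stack.images[0].shape[:2], z[0], dtype=np.int32)

    contrast = np.stack(
        [local_contrast_map(_to_grey(im, grey_projector), window)
         for im in stack.images]
    )
    selection = contrast.argmax(axis=0)  # argmax tie-breaks to lowest index
    selection = _majority_filter(selection, len(stack), MAJORITY_WINDOW)

    planes = np.stack(stack.images)
    if planes.ndim == 4:
        pixels = np.take_along_axis(
            planes, selection[None, :, :, None], axis=0
        )[0]
    else:
        pixels = np.take_along_axis(planes, selection[None, :, :], axis=0)[0]
    edof = EdofImage(
        pixels=pixels,
        perspective_id=stack.perspective_id,
        provenance=list(stack.filenames),
    )
    return edof, z[selection].astype(np.int32)
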