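"""Sharpness scoring and focus-based stack filtering.

A focal stack routinely contains planes in which nothing is in focus (the
focal plane lies in front of or behind the specimen).  Such planes carry no
information for blending and degrade alignment, so they are discarded before
stacking.  The scalar focus proxy is the variance of the response of a 3x3
Laplacian kernel: sharp, high-frequency content produces large positive and
negative excursions of the Laplacian, hence a large variance, while defocus
suppresses high frequencies and drives the variance toward zero.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve

from .errors import InvalidInputError
from .stack import ImageStack

logger = logging.getLogger(__name__)

#: 4-neighbour discrete Laplacian.
LAPLACIAN_3X3 = np.array([[0.0, 1.0, 0.0],
                          [1.0, -4.0, 1.0],
                          [0.0, 1.0, 0.0]])


def variance_of_laplacian(image: np.ndarray) -> float:
    """Population variance of the 3x3 Laplacian response of ``image``.

    RGB inputs are reduced with the channel-average grey projector first so
    the score matches the projection used for blending.  Borders are handled
    by reflect padding, keeping the response the same size as the input.

    Returns a non-negative float; exactly 0.0 iff the response is spatially
    constant (e.g. for a constant image).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("cannot score an empty image")
    if image.ndim == 3:
        image = image.mean(axis=2)
    elif image.ndim != 2:
        raise InvalidInputError(f"expected 2-D or 3-D image, got ndim={image.ndim}")
    response = convolve(image.astype(np.float64), LAPLACIAN_3X3, mode="reflect")
    return float(response.var())


def select_focused(
    stack: ImageStack,
    threshold: float = 0.0,
    csv_path: str | Path | None = None,
) -> ImageStack:
    """Sub-stack of planes whose focus score is >= ``threshold``.

    Order and image identity are preserved; planes scoring exactly at the
    threshold are retained.  Discarded z indices are logged, and the
    per-plane scores can optionally be written to a CSV
    (columns: filename, z_index, focus_score, retained).

    An empty result is legal (every plane out of focus) and logged as a
    warning.  The useful threshold depends on sensor noise, rail step size,
    aperture and magnification, so the default retains everything.
    """
    if threshold < 0:
        raise InvalidInputError("threshold must be non-negative")
    scores = [variance_of_laplacian(im) for im in stack.images]
    keep = [i for i, s in enumerate(scores) if s >= threshold]
    discarded = [stack.z_indices[i] for i in range(len(stack)) if i not in set(keep)]
    if discarded:
        logger.info("discarded out-of-focus planes z=%s (threshold %g)",
                    discarded, threshold)
    if not keep:
        logger.warning("no plane reached focus threshold %g; empty sub-stack",
                       threshold)
    if csv_path is not None:
        names = stack.filenames or [f"z{z:02d}" for z in stack.z_indices]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "z_index", "focus_score", "retained"])
            kept = set(keep)
            for i, (name, z, s) in enumerate(zip(names, stack.z_indices, scores)):
                writer.writerow([name, z, f"{s:.6f}", int(i in kept)])
    return stack.subset(keep)
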