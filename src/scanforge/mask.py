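"""Automatic specimen masking of EDOF images.

Scanned specimens sit in front of a near-uniform light-grey illumination
dome, and photogrammetry benefits greatly from removing that background.
The routine proceeds in five steps:

1. *enhance* — grey projection, Gaussian + median denoising, then CLAHE to
   strengthen the specimen outline;
2. *detect_outline* — an edge-probability map (smoothed gradient magnitude,
   or an externally trained structured-forest detector);
3. *largest_shape_mask* — binarise the edges, close and fill the contours,
   keep the largest connected shape (the specimen, possibly with enclosed
   background such as the area between a leg and the body);
4. *remove_infill* — flip background-like pixels inside the mask back to
   background using local-mean adaptive thresholding (a luminance-keying
   step that relies on the dome lighting being locally uniform);
5. *clean_mask* — connected-component labelling removes speckle components
   and fills pinholes below a resolution-dependent area threshold.

The mask is a boolean array (True = specimen); it is exported as a binary
PNG with white foreground, and can be applied to the EDOF image either as an
alpha channel or by zeroing background pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes, uniform_filter
from skimage import exposure, filters, measure, morphology

from .blend import EdofImage, grey_project
from .errors import ConfigurationError, InvalidInputError


class EmptyMaskWarning(UserWarning):
    """No closed specimen contour was found; the mask is empty."""


@dataclass
class MaskParams:
    """Tunables of the masking routine.

    ``gaussian_kernel`` / ``median_kernel`` are odd pixel widths of the
    denoising filters.  ``clahe_clip`` follows the OpenCV convention (a
    contrast-amplification limit, default 2.0) and ``clahe_tile`` is the
    CLAHE tile edge in pixels.  ``edge_threshold`` binarises the normalised
    edge map.  ``close_radius`` closes small gaps in the thresholded outline
    before filling.  ``adaptive_block`` / ``adaptive_offset`` control the
    local-mean keying step: a masked pixel is flipped to background when its
    intensity exceeds (local mean - adaptive_offset) on the 8-bit scale.
    ``min_component_fraction`` scales the speckle/pinhole area threshold
    with the image resolution.
    """

    gaussian_kernel: int = 5
    median_kernel: int = 5
    clahe_clip: float = 2.0
    clahe_tile: int = 64
    edge_threshold: float = 0.10
    close_radius: int = 3
    adaptive_block: int = 101
    adaptive_offset: float = -5.0
    min_component_fraction: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("gaussian_kernel", "median_kernel", "adaptive_block"):
            k = getattr(self, name)
            if k < 3 or k % 2 == 0:
                raise InvalidInputError(f"{name} must be an odd integer >= 3")
        if not (0 < self.min_component_fraction < 0.01):
            raise InvalidInputError("min_component_fraction must be in (0, 0.01)")
        if not (0 < self.edge_threshold < 1):
            raise InvalidInputError("edge_threshold must be in (0, 1)")


def _as_grey_u8(edof: EdofImage | np.ndarray) -> np.ndarray:
    pixels = edof.pixels if isinstance(edof, EdofImage) else np.asarray(edof)
    if pixels.ndim == 3:
        grey = grey_project(pixels, "average")
    else:
        grey = pixels.astype(np.float64)
    if np.issubdtype(pixels.dtype, np.integer):
        full = np.iinfo(pixels.dtype).max
        grey = grey * (255.0 / full)
    else:
        grey = grey * 255.0
    return np.clip(np.rint(grey), 0, 255).astype(np.uint8)


def enhance(edof: EdofImage | np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Denoise and contrast-enhance an EDOF image for edge detection.

    Grey projection, Gaussian blur, median blur, then CLAHE; returns an
    8-bit grey image of the same dimensions.  Constant images pass through
    unchanged (histogram equalisation is undefined at zero dynamic range).
    """
    params = params or MaskParams()
    grey = _as_grey_u8(edof)
    # sigma matching an NxN Gaussian kernel (OpenCV's kernel->sigma rule)
    sigma = 0.3 * ((params.gaussian_kernel - 1) * 0.5 - 1) + 0.8
    blurred = filters.gaussian(
        grey.astype(np.float64), sigma=sigma, mode="reflect"
    )
    blurred = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    footprint = np.ones((params.median_kernel, params.median_kernel), bool)
    denoised = filters.median(blurred, footprint=footprint)
    if np.ptp(denoised) == 0:
        return denoised
    equalised = exposure.equalize_adapthist(
        denoised,
        kernel_size=params.clahe_tile,
        clip_limit=params.clahe_clip / 100.0,
    )
    return np.clip(np.rint(equalised * 255.0), 0, 255).astype(np.uint8)


def detect_outline(
    enhanced: np.ndarray,
    detector: str = "gradient",
    forest_model: str | Path | None = None,
) -> np.ndarray:
    """Edge-probability map in [0, 1]; higher = more likely a boundary.

    ``gradient`` is self-contained: Scharr gradient magnitude of the
    enhanced image, normalised to [0, 1].  ``forest`` selects an externally
    trained structured-forest edge detector and requires its model file;
    requesting it without one is a configuration error (never a silent
    fallback).
    """
    if detector == "forest":
        if forest_model is None or not Path(forest_model).exists():
            raise ConfigurationError(
                "detector='forest' requires a structured-forest model file; "
                "none was found. Use detector='gradient' for the "
                "self-contained path."
            )
        raise ConfigurationError(
            "structured-forest inference backend is not available in this "
            "build; use detector='gradient'"
        )
    if detector != "gradient":
        raise InvalidInputError(f"unknown edge detector {detector!r}")
    grad = filters.scharr(np.asarray(enhanced, dtype=np.float64))
    peak = grad.max()
    return grad / peak if peak > 0 else grad


def largest_shape_mask(
    edges: np.ndarray, threshold: float, close_radius: int = 3
) -> np.ndarray:
    """Binarise edges, close and fill contours, keep the largest shape.

    Returns a boolean mask (True = specimen candidate).  When no foreground
    survives, an empty mask is returned and an :class:`EmptyMaskWarning` is
    issued.
    """
    if not (0 < threshold < 1):
        raise InvalidInputError("threshold must be in (0, 1)")
    binary = np.asarray(edges) >= threshold
    closed = morphology.closing(binary, morphology.disk(close_radius))
    filled = binary_fill_holes(closed)
    labels = measure.label(filled, connectivity=2)
    if labels.max() == 0:
        warnings.warn("no closed contour found; mask is empty", EmptyMaskWarning)
        return np.zeros_like(binary, dtype=bool)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == areas.argmax()


def remove_infill(
    mask: np.ndarray,
    edof: EdofImage | np.ndarray,
    params: MaskParams | None = None,
) -> np.ndarray:
    """Flip background-like pixels inside the mask back to background.

    Local-mean adaptive thresholding of the grey EDOF (luminance keying):
    pixels brighter than their neighbourhood mean minus ``adaptive_offset``
    match the light dome background and are removed from the foreground.
    Only current foreground can change; background never flips to
    foreground here.
    """
    params = params or MaskParams()
    mask = np.asarray(mask, dtype=bool)
    grey = _as_grey_u8(edof).astype(np.float64)
    if mask.shape != grey.shape:
        raise InvalidInputError("mask and EDOF image dimensions differ")
    local_mean = uniform_filter(grey, size=params.adaptive_block, mode="reflect")
    background_like = grey > (local_mean - params.adaptive_offset)
    return mask & ~background_like


def clean_mask(mask: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Remove speckle components and fill pinholes below the area threshold.

    The threshold is ``min_component_fraction`` of the pixel count
    (components of exactly the threshold area are retained/kept as holes).
    The largest foreground component is always retained.  Foreground uses
    8-connectivity, background 4-connectivity (the standard dual pair).
    """
    params = params or MaskParams()
    mask = np.asarray(mask, dtype=bool)
    min_area = params.min_component_fraction * mask.size

    labels = measure.label(mask, connectivity=2)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        keep = areas >= min_area
        keep[areas.argmax()] = True  # largest component always survives
        mask = keep[labels]
        mask[labels == 0] = False

    holes = measure.label(~mask, connectivity=1)
    if holes.max() > 0:
        hole_areas = np.bincount(holes.ravel())
        hole_areas[0] = 0
        fill = (hole_areas > 0) & (hole_areas < min_area)
        mask = mask | fill[holes]
    return mask


def apply_cutout(
    edof: EdofImage | np.ndarray,
    mask: np.ndarray,
    mode: str = "zero",
) -> np.ndarray:
    """Apply a binary mask to an EDOF image.

    ``alpha`` returns an RGBA image whose alpha channel is 255 x mask;
    ``zero`` returns the image with background pixels set to 0.  Foreground
    pixels are bit-identical to the input in both modes.
    """
    pixels = edof.pixels if isinstance(edof, EdofImage) else np.asarray(edof)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape[:2]:
        raise InvalidInputError("mask and image dimensions differ")
    if mode == "zero":
        out = pixels.copy()
        out[~mask] = 0
        return out
    if mode == "alpha":
        if pixels.ndim == 2:
            pixels = np.repeat(pixels[:, :, None], 3, axis=2)
        if np.issubdtype(pixels.dtype, np.integer):
            opaque = np.iinfo(pixels.dtype).max
        else:
            opaque = 1.0
        alpha = np.where(mask, opaque, 0).astype(pixels.dtype)
        return np.dstack([pixels, alpha])
    raise InvalidInputError(f"unknown cut-out mode {mode!r}")


def mask_pipeline(
    edof: EdofImage | np.ndarray,
    params: MaskParams | None = None,
    cutout_mode: str = "zero",
    detector: str = "gradient",
    forest_model: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The full five-step masking routine; returns (mask, cut-out).

    Deterministic: identical inputs and parameters give bit-identical
    results.  An empty-mask warning from the contour step propagates.
    """
    params = params or MaskParams()
    enhanced = enhance(edof, params)
    edges = detect_outline(enhanced, detector=detector, forest_model=forest_model)
    mask = largest_shape_mask(edges, params.edge_threshold, params.close_radius)
    mask = remove_infill(mask, edof, params)
    mask = clean_mask(mask, params)
    return mask, apply_cutout(edof, mask, mode=cutout_mode)


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write the mask as an 8-bit binary PNG (white = specimen)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
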