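"""Scale + translation registration of a focal stack to its distal plane.

As the camera advances along its rail the effective magnification grows, and
small rail imperfections jitter the image in x and y.  Both effects are well
described by an isotropic scale about the image centre plus a translation;
rotation and shear are excluded because the rig constrains camera motion to
the optical axis.  The most distal plane (z index 0, widest field of view) is
the reference frame, and every other plane is resampled into it.

Because the in-focus overlap between distant focal planes is shallow, each
plane is registered against its z-neighbour and the per-pair transforms are
composed through to the reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform as _SkTransform, warp

from .errors import InvalidInputError
from .stack import ImageStack

logger = logging.getLogger(__name__)

#: magnification search interval for the scale estimate; a focus-stack step
#: changes magnification by at most a few percent.
SCALE_BOUNDS = (0.93, 1.08)


@dataclass(frozen=True)
class SimilarityTransform:
    """Isotropic scale about the image centre plus a translation, in pixels.

    The transform describes the displacement of the *moving* image relative
    to the reference: ``moving ≈ T(reference)`` with
    ``T(p) = scale * (p - c) + c + (tx, ty)`` for pixel position ``p = (x, y)``
    and image centre ``c``.  ``score`` is a registration confidence in
    [0, 1]; featureless inputs yield the identity with score 0.
    """

    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    score: float = 1.0

    def compose(self, outer: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``self`` then ``outer``.

        Both factors share the same centre ``c``; the family is closed under
        composition: scale multiplies, translation is
        ``outer.scale * t_self + t_outer``.
        """
        return SimilarityTransform(
            scale=self.scale * outer.scale,
            tx=outer.scale * self.tx + outer.tx,
            ty=outer.scale * self.ty + outer.ty,
            score=min(self.score, outer.score),
        )

    @property
    def is_identity(self) -> bool:
        return self.scale == 1.0 and self.tx == 0.0 and self.ty == 0.0


def _centre(shape) -> np.ndarray:
    h, w = shape[:2]
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def _sk_tform(t: SimilarityTransform, shape) -> _SkTransform:
    """skimage transform with the same reference->moving mapping."""
    c = _centre(shape)
    return (
        _SkTransform(translation=-c)
        + _SkTransform(scale=t.scale)
        + _SkTransform(translation=c)
        + _SkTransform(translation=(t.tx, t.ty))
    )


def _as_grey_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=2)
    return image


def _undo_scale(moving: np.ndarray, scale: float) -> np.ndarray:
    """Resample ``moving`` so a content magnification ``scale`` is removed."""
    c = _centre(moving.shape)
    tf = (
        _SkTransform(translation=-c)
        + _SkTransform(scale=scale)
        + _SkTransform(translation=c)
    )
    return warp(moving, tf, order=1, mode="edge")


def register_pair(
    reference: np.ndarray,
    moving: np.ndarray,
    scale_bounds: tuple[float, float] = SCALE_BOUNDS,
) -> SimilarityTransform:
    """Estimate the scale + translation of ``moving`` relative to ``reference``.

    The scale is found by a bounded golden-section search minimising the
    phase-correlation error after the candidate magnification is removed;
    the translation then comes from sub-pixel phase correlation.  The result
    is deterministic for fixed inputs.

    Featureless (constant) images cannot be registered; the identity is
    returned with ``score`` 0 and a warning is logged.
    """
    ref = _as_grey_float(reference)
    mov = _as_grey_float(moving)
    if ref.shape != mov.shape:
        raise InvalidInputError("register_pair requires equal image dimensions")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        logger.warning("featureless image in register_pair; returning identity")
        return SimilarityTransform(score=0.0)

    def correlation_error(scale: float) -> tuple[float, np.ndarray]:
        unscaled = _undo_scale(mov, scale)
        shift, error, _ = phase_cross_correlation(
            ref, unscaled, upsample_factor=20, normalization=None
        )
        return float(error), shift

    res = minimize_scalar(
        lambda s: correlation_error(s)[0],
        bounds=scale_bounds,
        method="bounded",
        options={"xatol": 1e-4},
    )
    scale = float(res.x)
    error, shift = correlation_error(scale)
    # identity is an exact fixed point: prefer it when it does no worse
    id_error, id_shift = correlation_error(1.0)
    if id_error <= error:
        scale, error, shift = 1.0, id_error, id_shift
    # phase_cross_correlation returns the (row, col) shift that moves
    # ``moving`` onto ``reference``; the displacement of moving is its
    # negation.  Undoing a magnification s maps a displacement t to t/s, so
    # the measured residual is scaled back up.
    ty, tx = (-shift * scale).tolist()
    return SimilarityTransform(
        scale=scale, tx=float(tx), ty=float(ty),
        score=float(np.clip(1.0 - error, 0.0, 1.0)),
    )


def apply_transform(image: np.ndarray, t: SimilarityTransform) -> np.ndarray:
    """Resample ``image`` into the reference frame (inverse of ``t``).

    Bilinear interpolation; out-of-frame pixels are filled by edge
    replication (by construction they fall in background).  The dtype of the
    input is preserved.
    """
    if t.is_identity:
        return image
    dtype = image.dtype
    tf = _sk_tform(t, image.shape)
    out = warp(image.astype(np.float64), tf, order=1, mode="edge")
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(dtype)


def align_stack(
    stack: ImageStack,
) -> tuple[ImageStack, list[SimilarityTransform]]:
    """Register every plane to the most distal plane and resample.

    The plane at position 0 is unchanged and acts as the reference.  Each
    subsequent plane is registered against its z-neighbour and the pairwise
    transforms are composed through to the reference, which tolerates the
    shallow focus overlap between distant planes.  Never fails outright:
    low-confidence registrations propagate their flag in ``score``.
    """
    if len(stack) == 0:
        raise InvalidInputError("cannot align an empty stack")
    transforms = [SimilarityTransform()]
    aligned = [stack.images[0]]
    for i in range(1, len(stack)):
        pair = register_pair(stack.images[i - 1], stack.images[i])
        total = pair.compose(transforms[i - 1])
        transforms.append(total)
        aligned.append(apply_transform(stack.images[i], total))
    out = ImageStack(
        images=aligned,
        z_indices=list(stack.z_indices),
        perspective_id=stack.perspective_id,
        filenames=list(stack.filenames),
    )
    return out, transforms


def write_transform_sidecar(
    path: str | Path,
    stack: ImageStack,
    transforms: list[SimilarityTransform],
) -> None:
    """Record per-image transforms as a JSON sidecar."""
    names = stack.filenames or [f"z{z:02d}" for z in stack.z_indices]
    records = [
        {"filename": name, **asdict(t)} for name, t in zip(names, transforms)
    ]
    Path(path).write_text(json.dumps(records, indent=2, sort_keys=True))
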