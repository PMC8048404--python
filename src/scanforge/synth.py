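"""Seeded synthetic fixtures with ground truth for every processing stage.

Real scans cannot ship with a software package, so each stage is exercised
on generated data that reproduces the relevant physics at a useful level of
abstraction: depth-dependent defocus across a focal stack (Gaussian blur
with sigma linear in the depth offset), magnification growth and rail jitter
(recorded scale/translation per plane), a dark articulated specimen on a
near-uniform light-grey dome background with mild vignetting, planar
gauge-block meshes of known step height, and normal samples of specified
coefficient of variation.  Every generator is a pure function of its spec,
seed included: the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw, morphology
import trimesh

from .align import SimilarityTransform, apply_transform
from .blend import EdofImage
from .errors import InvalidInputError
from .metrology import RegionSpec
from .stack import ImageStack


@dataclass
class FixtureSpec:
    """Parameters of the synthetic focal-stack / specimen generators.

    ``blur_scale`` is the defocus sigma (px) added per plane of depth
    offset; ``scale_step`` and ``jitter_px`` describe per-plane
    magnification growth and rail jitter; ``noise_sigma`` is pixel noise as
    a fraction of the intensity range; ``background`` is the dome grey on
    the 8-bit scale with ``vignette`` as a relative corner falloff;
    ``separation`` is the specimen/background grey-level separation.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    n_planes: int = 3
    blur_scale: float = 2.5
    scale_step: float = 0.0
    jitter_px: float = 0.0
    noise_sigma: float = 0.0
    background: int = 200
    vignette: float = 0.08
    separation: int = 140


def _texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Multi-scale random texture in [0, 1] with strong fine detail."""
    fine = gaussian_filter(rng.standard_normal(shape), 1.0)
    mid = gaussian_filter(rng.standard_normal(shape), 4.0)
    coarse = gaussian_filter(rng.standard_normal(shape), 16.0)
    tex = 1.4 * fine + 1.0 * mid + 0.8 * coarse
    tex -= tex.min()
    peak = tex.max()
    return tex / peak if peak > 0 else tex


def make_focal_stack(
    spec: FixtureSpec,
) -> tuple[ImageStack, np.ndarray, np.ndarray, list[SimilarityTransform]]:
    """Render a focal stack with known all-in-focus ground truth.

    The scene is split into ``n_planes`` vertical bands; band ``j`` is in
    focus on plane ``j`` and blurred with sigma = ``blur_scale * |i - j|``
    on plane ``i``.  Optional per-plane magnification (``1 + scale_step*i``)
    and jitter are applied after blurring and recorded as ground-truth
    transforms (displacement of each plane relative to plane 0).  Returns
    ``(stack, ground-truth sharp image, ground-truth index map,
    ground-truth transforms)``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    gt = (20.0 + 215.0 * _texture(rng, (h, w)))
    gt_u8 = np.clip(np.rint(gt), 0, 255).astype(np.uint8)

    bands = np.minimum(
        (np.arange(w) * spec.n_planes) // w, spec.n_planes - 1
    )
    gt_index = np.broadcast_to(bands, (h, w)).astype(np.int32).copy()

    transforms: list[SimilarityTransform] = []
    images: list[np.ndarray] = []
    for i in range(spec.n_planes):
        plane = np.empty((h, w))
        blurred_cache: dict[float, np.ndarray] = {}
        for j in range(spec.n_planes):
            sigma = spec.blur_scale * abs(i - j)
            if sigma not in blurred_cache:
                blurred_cache[sigma] = (
                    gt if sigma == 0 else gaussian_filter(gt, sigma)
                )
            cols = bands == j
            plane[:, cols] = blurred_cache[sigma][:, cols]
        if i == 0 or (spec.scale_step == 0 and spec.jitter_px == 0):
            t = SimilarityTransform()
        else:
            t = SimilarityTransform(
                scale=1.0 + spec.scale_step * i,
                tx=float(rng.uniform(-spec.jitter_px, spec.jitter_px)),
                ty=float(rng.uniform(-spec.jitter_px, spec.jitter_px)),
            )
        transforms.append(t)
        if not t.is_identity:
            # forward-render the displacement: resample with the inverse of
            # the inverse, i.e. apply_transform undoes t, so warp with t's
            # inverse displacement
            inv = SimilarityTransform(
                scale=1.0 / t.scale, tx=-t.tx / t.scale, ty=-t.ty / t.scale
            )
            plane = apply_transform(plane, inv)
        if spec.noise_sigma > 0:
            plane = plane + rng.normal(0, spec.noise_sigma * 255.0, plane.shape)
        images.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))

    stack = ImageStack(
        images=images,
        z_indices=list(range(spec.n_planes)),
        perspective_id=(0.0, 0.0),
        filenames=[f"x+000_y000_z{i:02d}.png" for i in range(spec.n_planes)],
    )
    return stack, gt_u8, gt_index, transforms


def make_specimen_edof(spec: FixtureSpec) -> tuple[EdofImage, np.ndarray]:
    """Synthetic specimen EDOF image with ground-truth mask.

    A dark articulated body (two body segments, head, six leg-like
    appendages) with one enclosed background region inside the body, on a
    light-grey background with mild vignetting, matching the uniform-dome
    lighting assumption of the masking routine.  Returns the image and the
    boolean ground-truth mask (True = specimen; the enclosed region is
    background).
    """
    if spec.separation <= 0:
        raise InvalidInputError(
            "specimen fixture unusable: foreground/background separation is 0"
        )
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cy, cx = h / 2.0, w / 2.0
    scale = min(h, w) / 256.0

    body = np.zeros((h, w), bool)
    rr, cc = draw.ellipse(cy + 12 * scale, cx, 52 * scale, 34 * scale,
                          shape=(h, w), rotation=0.25)
    body[rr, cc] = True
    rr, cc = draw.ellipse(cy - 48 * scale, cx - 10 * scale, 26 * scale,
                          20 * scale, shape=(h, w))
    body[rr, cc] = True  # thorax
    rr, cc = draw.disk((cy - 82 * scale, cx - 16 * scale), 14 * scale,
                       shape=(h, w))
    body[rr, cc] = True  # head

    legs = np.zeros((h, w), bool)
    anchors = [(-40, -16), (-40, -16), (-10, 0), (-10, 0), (30, 8), (30, 8)]
    tips = [(-105, -95), (-120, 60), (-45, -110), (-20, 105),
            (80, -90), (100, 85)]
    for (ay, ax), (ty, tx) in zip(anchors, tips):
        rr, cc = draw.line(
            int(cy + ay * scale), int(cx + ax * scale),
            int(np.clip(cy + ty * scale, 0, h - 1)),
            int(np.clip(cx + tx * scale, 0, w - 1)),
        )
        legs[rr, cc] = True
    legs = morphology.dilation(legs, morphology.disk(max(3, int(4 * scale))))

    hole = np.zeros((h, w), bool)
    rr, cc = draw.ellipse(cy + 8 * scale, cx + 6 * scale, 13 * scale,
                          9 * scale, shape=(h, w), rotation=0.4)
    hole[rr, cc] = True

    gt_mask = (body | legs) & ~hole

    bg_level = float(spec.background)
    fg_level = bg_level - float(spec.separation)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2
    image = bg_level * (1.0 - spec.vignette * r2 / 2.0)
    fg_texture = fg_level + 22.0 * (2.0 * _texture(rng, (h, w)) - 1.0)
    image[gt_mask] = fg_texture[gt_mask]
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma * 255.0, image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return EdofImage(pixels=pixels, perspective_id=(0.0, 0.0)), gt_mask


def _plate_mesh(
    side_mm: float,
    height_mm: float,
    n_vertices: int,
    origin_x: float,
    rng: np.random.Generator,
    noise_sd: float,
) -> trimesh.Trimesh:
    s = max(2, int(round(np.sqrt(n_vertices))))
    xs = np.linspace(origin_x, origin_x + side_mm, s)
    ys = np.linspace(0.0, side_mm, s)
    xx, yy = np.meshgrid(xs, ys)
    zz = np.full_like(xx, height_mm)
    if noise_sd > 0:
        zz = zz + rng.normal(0, noise_sd, zz.shape)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for r in range(s - 1):
        for c in range(s - 1):
            a = r * s + c
            faces.append([a, a + 1, a + s])
            faces.append([a + 1, a + s + 1, a + s])
    return trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)


@dataclass
class StepCubeFixture:
    """Gauge-block pair fixture: meshes, selection regions, true step (mm)."""

    mesh: trimesh.Trimesh
    mesh_top: trimesh.Trimesh
    mesh_ref: trimesh.Trimesh
    top_region: RegionSpec
    ref_region: RegionSpec
    true_step_mm: float
    heights_mm: tuple[float, float] = field(default=(0.0, 0.0))


def make_step_cubes(
    heights: tuple[float, float],
    noise_sd: float = 0.0,
    n_vertices: int = 10_000,
    seed: int = 0,
    side_mm: float = 5.0,
    gap_mm: float = 2.0,
) -> StepCubeFixture:
    """Top-plane meshes of two gauge blocks laid side by side.

    ``heights`` are the block heights in mm (top block first); the true step
    is their difference.  ``noise_sd`` adds i.i.d. vertical vertex noise
    (mm) emulating reconstruction roughness; with zero noise every face is
    exactly planar.
    """
    h_top, h_ref = heights
    rng = np.random.default_rng(seed)
    mesh_top = _plate_mesh(side_mm, h_top, n_vertices, 0.0, rng, noise_sd)
    mesh_ref = _plate_mesh(
        side_mm, h_ref, n_vertices, side_mm + gap_mm, rng, noise_sd
    )
    combined = trimesh.util.concatenate([mesh_top, mesh_ref])
    pad = 0.5 + 10 * noise_sd
    top_region = RegionSpec(
        (-0.1, -0.1, h_top - pad), (side_mm + 0.1, side_mm + 0.1, h_top + pad),
        label="top",
    )
    ref_region = RegionSpec(
        (side_mm + gap_mm - 0.1, -0.1, h_ref - pad),
        (2 * side_mm + gap_mm + 0.1, side_mm + 0.1, h_ref + pad),
        label="reference",
    )
    return StepCubeFixture(
        mesh=combined,
        mesh_top=mesh_top,
        mesh_ref=mesh_ref,
        top_region=top_region,
        ref_region=ref_region,
        true_step_mm=float(h_top - h_ref),
        heights_mm=(float(h_top), float(h_ref)),
    )


def make_cv_groups(
    k: int,
    n: int,
    true_cvs: list[float],
    means: list[float],
    seed: int = 0,
) -> list[np.ndarray]:
    """Normal samples per group with the requested means and CVs."""
    if len(true_cvs) != k or len(means) != k:
        raise InvalidInputError("true_cvs and means must have length k")
    rng = np.random.default_rng(seed)
    return [
        rng.normal(mu, cv_i * mu, size=n)
        for mu, cv_i in zip(means, true_cvs)
    ]
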