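"""End-to-end orchestration: stack -> align -> blend -> mask -> tag -> poses.

Each viewing perspective lives in its own subdirectory of the input
directory (named ``x{+/-ddd}_y{ddd}``) holding the z-indexed focal-stack
images.  Perspectives are processed independently — any processing order
yields identical outputs — and a scene file with the analytic camera-pose
priors for the full angle grid is written last.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio

from .align import align_stack, write_transform_sidecar
from .blend import blend_hard_mask
from .config import ProjectConfig
from .errors import InvalidInputError
from .focus import select_focused
from .mask import mask_pipeline, save_mask_png
from .metadata import write_exif
from .poses import ScanConfig, pose_grid, write_sfm
from .stack import load_stack

logger = logging.getLogger(__name__)

PERSPECTIVE_RE = re.compile(r"^x(?P<x>[+-]?\d+)_y(?P<y>\d+)$")


@dataclass
class PerspectiveReport:
    perspective: str
    n_input: int
    n_retained: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    perspectives: list[PerspectiveReport]
    sfm_path: str

    @property
    def n_warnings(self) -> int:
        return sum(len(p.warnings) for p in self.perspectives)


def _process_perspective(
    subdir: Path, out_dir: Path, config: ProjectConfig
) -> PerspectiveReport:
    m = PERSPECTIVE_RE.match(subdir.name)
    pid = (float(m.group("x")), float(m.group("y"))) if m else (0.0, 0.0)
    stack = load_stack(subdir, perspective_id=pid)
    n_input = len(stack)
    report = PerspectiveReport(subdir.name, n_input, n_input)

    focused = select_focused(
        stack, config.focus_threshold,
        csv_path=out_dir / f"{subdir.name}_focus.csv",
    )
    report.n_retained = len(focused)
    if len(focused) == 0:
        report.warnings.append("no in-focus planes; perspective skipped")
        return report

    aligned, transforms = align_stack(focused)
    write_transform_sidecar(
        out_dir / f"{subdir.name}_transforms.json", aligned, transforms
    )
    edof, _ = blend_hard_mask(
        aligned, window=config.blend_window, grey_projector=config.grey_projector
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mask, cutout = mask_pipeline(
            edof, config.mask_params, cutout_mode=config.cutout_mode
        )
        report.warnings.extend(str(w.message) for w in caught)

    edof_path = out_dir / f"{subdir.name}_edof.png"
    iio.imwrite(edof_path, edof.pixels)
    save_mask_png(out_dir / f"{subdir.name}_mask.png", mask)
    cutout_path = out_dir / f"{subdir.name}_cutout.png"
    iio.imwrite(cutout_path, cutout)
    if config.intrinsics.make:
        write_exif(cutout_path, config.intrinsics)
        write_exif(edof_path, config.intrinsics)
    return report


def run_pipeline(config: ProjectConfig) -> RunReport:
    """Process every perspective of a project and emit the pose-prior scene.

    Raises for an empty or missing input directory (no partial outputs);
    per-perspective warnings propagate into the report without aborting the
    other perspectives.  Deterministic for a fixed config.
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise InvalidInputError(f"input directory not found: {input_dir}")
    subdirs = sorted(p for p in input_dir.iterdir() if p.is_dir())
    if not subdirs:
        raise InvalidInputError(f"no perspective subdirectories in {input_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reports = []
    for subdir in subdirs:
        logger.info("processing perspective %s", subdir.name)
        reports.append(_process_perspective(subdir, out_dir, config))

    x_angles = config.x_axis.angles()
    y_angles = config.y_axis.angles()
    names = [
        f"x{int(round(x)):+04d}_y{int(round(y)):03d}_cutout.png"
        for x in x_angles for y in y_angles
    ]
    scene = pose_grid(ScanConfig(
        x_angles_deg=x_angles,
        y_angles_deg=y_angles,
        radius=config.radius_mm,
        intrinsics=config.intrinsics,
        image_names=names,
    ))
    sfm_path = out_dir / "scene.sfm"
    write_sfm(scene, sfm_path)
    return RunReport(perspectives=reports, sfm_path=str(sfm_path))
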