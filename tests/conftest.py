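import numpy as np
import pytest

import scanforge as sf


@pytest.fixture(scope="session")
def specimen_fixture():
    """Clean synthetic specimen EDOF image with ground-truth mask."""
    spec = sf.FixtureSpec(seed=11, shape=(512, 512), noise_sigma=0.0)
    edof, gt_mask = sf.make_specimen_edof(spec)
    return edof, gt_mask


@pytest.fixture(scope="session")
def three_plane_stack():
    """3-plane focal stack with ground truth (no transforms)."""
    spec = sf.FixtureSpec(seed=3, shape=(256, 256), n_planes=3, blur_scale=2.5)
    return sf.make_focal_stack(spec)


@pytest.fixture(scope="session")
def textured_image():
    """Deterministic textured grey image for registration/scoring tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(17)
    return gaussian_filter(rng.random((256, 256)) * 255.0, 1.5)


@pytest.fixture
def intrinsics():
    return sf.CameraIntrinsics(
        make="FLIR",
        model="BFS-U3-200S6C-C",
        serial="SN0001",
        focal_length_mm=35.0,
        focal_length_35mm=95.0,
        sensor_width_mm=13.1,
        image_width_px=5472,
        image_height_px=3648,
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
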