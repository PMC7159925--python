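import numpy as np
import pytest

from mtanchor.core_io import ImageStack, PolylineRoi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def axis_roi(stack: ImageStack, width_px: int = 3, y: float | None = None) -> PolylineRoi:
    """Straight polyline along the neurite axis of a synthetic movie."""
    if y is None:
        y = stack.shape[1] // 2
    return PolylineRoi([(0, y), (stack.shape[2] - 1, y)], width_px=width_px)


def bilinear(img: np.ndarray, x: float, y: float) -> float:
    """Reference bilinear interpolation, written independently of scipy."""
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, img.shape[1] - 1), min(y0 + 1, img.shape[0] - 1)
    fx, fy = x - x0, y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x1] * fx * (1 - fy)
        + img[y1, x0] * (1 - fx) * fy
        + img[y1, x1] * fx * fy
    )
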