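"""Image, ROI and metadata I/O plus the geometric sampling primitives shared by all assays.

Conventions used throughout the package:

* coordinates are 0-based, continuous, ordered ``(x, y)`` = (column, row);
* intervals are half-open;
* physical lengths convert to pixels by rounding to the nearest integer pixel;
* image stacks are indexed ``(frame, row, column)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

#: µm per pixel for the two camera/objective combinations used for live imaging
#: (spinning-disk confocal with the extra 2.0x lens): 110 nm at 60x, 67 nm at 100x.
PIXEL_SIZE_PRESETS_UM = {"60x": 0.110, "100x": 0.067}

#: Default anatomical orientation: the cell body sits at low x / low arc index.
ORIGIN_CB_LOW = "cell body at low x"
ORIGIN_CB_HIGH = "cell body at high x"


def cell_body_at_low_index(origin_label: str) -> bool:
    """Interpret an origin label: True if the cell body is at the low-coordinate end."""
    return "high" not in origin_label.lower()


@dataclass
class ImageStack:
    """A time-lapse grayscale movie with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Intensities in arbitrary non-negative units.
    pixel_size_um : float
        Isotropic pixel size in µm.
    frame_interval_s : float
        Seconds between consecutive frames.
    origin_label : str
        Free-text anatomical reference, e.g. ``"cell body at low x"``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    origin_label: str = ORIGIN_CB_LOW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be a (frame, row, column) array with >=1 frame")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PolylineRoi:
    """An ordered open polyline with a transverse averaging width.

    ``vertices`` are continuous 0-based (x, y) pixel coordinates; ``width_px`` is the
    number of 1-px-spaced samples taken perpendicular to the path at each arc step.
    """

    vertices: Sequence[tuple[float, float]]
    width_px: int = 1

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 2:
            raise ValueError("polyline needs >=2 vertices")
        for (x0, y0), (x1, y1) in zip(self.vertices[:-1], self.vertices[1:]):
            if math.hypot(x1 - x0, y1 - y0) == 0:
                raise ValueError("consecutive polyline vertices must not coincide")
        if int(self.width_px) != self.width_px or self.width_px < 1:
            raise ValueError("width_px must be an integer >= 1")
        self.width_px = int(self.width_px)

    def arc_length_px(self) -> float:
        v = np.asarray(self.vertices)
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))

    def arc_length_um(self, pixel_size_um: float) -> float:
        return self.arc_length_px() * pixel_size_um


@dataclass
class CircleRoi:
    """A circular ROI given by its center (x, y) and diameter in pixels."""

    center: tuple[float, float]
    diameter_px: float

    def __post_init__(self) -> None:
        if not self.diameter_px > 0:
            raise ValueError("diameter_px must be > 0")


@dataclass
class BoxRoi:
    """An axis-aligned box with a pixel-space corner and a physical extent in µm."""

    corner: tuple[float, float]
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError("width_um and height_um must be > 0")

    def to_pixel_window(self, pixel_size_um: float) -> tuple[int, int, int, int]:
        """Return (x0, y0, w_px, h_px) with dimensions rounded to the nearest pixel."""
        x0 = int(round(self.corner[0]))
        y0 = int(round(self.corner[1]))
        w = int(round(self.width_um / pixel_size_um))
        h = int(round(self.height_um / pixel_size_um))
        return x0, y0, w, h


# ---------------------------------------------------------------------------
# stack / metadata / ROI file I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    origin_label: str = ORIGIN_CB_LOW,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Integer data are widened to float64 without rescaling. RGB input is rejected;
    calibration always comes from the arguments (typically a YAML sidecar), never
    from TIFF tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.photometric in (tifffile.PHOTOMETRIC.RGB, tifffile.PHOTOMETRIC.PALETTE):
            raise ValueError("RGB/palette TIFF not supported; grayscale only")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a T x Y x X grayscale TIFF, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("zero-frame TIFF")
    return ImageStack(arr.astype(np.float64), pixel_size_um, frame_interval_s, origin_label)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF (frames in order, values untouched)."""
    data = stack.data
    if np.allclose(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        data = np.round(data).astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_metadata(path: str | Path) -> dict:
    """Read a YAML sidecar with pixel_size_um, frame_interval_s and origin_label."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("pixel_size_um", "frame_interval_s"):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing required field {key!r}")
        if not meta[key] > 0:
            raise ValueError(f"metadata field {key!r} must be > 0, got {meta[key]}")
    meta.setdefault("origin_label", ORIGIN_CB_LOW)
    return meta


def write_metadata(meta: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh)


def roi_to_dict(roi) -> dict:
    if isinstance(roi, PolylineRoi):
        return {"type": "polyline", "vertices": list(map(list, roi.vertices)),
                "width_px": roi.width_px}
    if isinstance(roi, CircleRoi):
        return {"type": "circle", "center": list(roi.center), "diameter_px": roi.diameter_px}
    if isinstance(roi, BoxRoi):
        return {"type": "box", "corner": list(roi.corner),
                "width_um": roi.width_um, "height_um": roi.height_um}
    raise TypeError(f"unknown ROI type: {type(roi)!r}")


def roi_from_dict(d: dict):
    kind = d.get("type")
    if kind == "polyline":
        return PolylineRoi([tuple(v) for v in d["vertices"]], d.get("width_px", 1))
    if kind == "circle":
        return CircleRoi(tuple(d["center"]), d["diameter_px"])
    if kind == "box":
        return BoxRoi(tuple(d["corner"]), d["width_um"], d["height_um"])
    raise ValueError(f"unknown ROI type {kind!r}")


def load_rois(path: str | Path):
    """Load one ROI or a dict/list of ROIs from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict) and "type" in payload:
        return roi_from_dict(payload)
    if isinstance(payload, list):
        return [roi_from_dict(d) for d in payload]
    return {name: roi_from_dict(d) for name, d in payload.items()}


def save_rois(rois, path: str | Path) -> None:
    if isinstance(rois, (PolylineRoi, CircleRoi, BoxRoi)):
        payload = roi_to_dict(rois)
    elif isinstance(rois, dict):
        payload = {name: roi_to_dict(r) for name, r in rois.items()}
    else:
        payload = [roi_to_dict(r) for r in rois]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# geometric sampling
# ---------------------------------------------------------------------------

def _polyline_points(roi: PolylineRoi) -> tuple[np.ndarray, np.ndarray]:
    """Resample the polyline at exact 1-px arc-length steps.

    Returns (points, normals): points is (n, 2) (x, y) positions, one per step,
    n = floor(arc length) + 1; normals is the unit normal of the containing segment.
    """
    v = np.asarray(roi.vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = int(math.floor(total)) + 1
    s = np.arange(n_samples, dtype=float)
    # segment index for each arc position (last position maps into the last segment)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pts = v[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / seg_len[idx][:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    return pts, normals


def sample_polyline(
    frame: np.ndarray,
    roi: PolylineRoi,
    mode: Literal["max", "mean"] = "max",
) -> np.ndarray:
    """Sample intensities along a polyline at 1-px arc steps, reslice-style.

    At each arc step, ``width_px`` bilinear samples are taken at 1-px spacing
    perpendicular to the local path direction (centered on the path) and reduced
    by ``max`` (default) or ``mean``. Output length is floor(arc length) + 1.

    The path itself must lie within the frame; transverse samples that would fall
    outside are clipped to the border (with a logged warning).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if mode not in ("max", "mean"):
        raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
    h, w = frame.shape
    pts, normals = _polyline_points(roi)
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
        raise ValueError("polyline ROI lies outside the image bounds")

    offsets = np.arange(roi.width_px, dtype=float) - (roi.width_px - 1) / 2.0
    # (n, width, 2) sample positions
    sample_xy = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = sample_xy[..., 0], sample_xy[..., 1]
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        logger.warning("transverse width extends past the image border; samples clipped")
        xs = np.clip(xs, 0, w - 1)
        ys = np.clip(ys, 0, h - 1)
    vals = ndimage.map_coordinates(frame, [ys.ravel(), xs.ravel()], order=1)
    vals = vals.reshape(xs.shape)
    return vals.max(axis=1) if mode == "max" else vals.mean(axis=1)


def sum_project(stack: ImageStack, frame_range: tuple[int, int]) -> np.ndarray:
    """Sum the frames in the half-open interval ``frame_range`` element-wise."""
    a, b = frame_range
    if not (0 <= a < b <= stack.n_frames):
        raise ValueError(f"frame_range {frame_range} invalid for {stack.n_frames} frames")
    return stack.data[a:b].sum(axis=0)


def integrated_density(image: np.ndarray, box: BoxRoi, pixel_size_um: float) -> float:
    """Sum of pixel intensities inside a physically sized box.

    The box is converted to a pixel window by rounding each dimension to the
    nearest integer pixel; the window must fit inside the image.
    """
    image = np.asarray(image, dtype=float)
    x0, y0, w, h = box.to_pixel_window(pixel_size_um)
    if x0 < 0 or y0 < 0 or x0 + w > image.shape[1] or y0 + h > image.shape[0]:
        raise ValueError("box extends outside the image")
    return float(image[y0:y0 + h, x0:x0 + w].sum())


def circle_mean(image: np.ndarray, roi: CircleRoi) -> float:
    """Mean of pixels whose centers fall inside the circle."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = roi.center
    r = roi.diameter_px / 2.0
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
        raise ValueError("circle ROI extends outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if not mask.any():
        raise ValueError("circle ROI contains no pixel centers")
    return float(image[mask].mean())
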