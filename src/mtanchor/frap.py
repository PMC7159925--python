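"""FRAP double-normalization and immobile-fraction estimation.

The normalization chain, applied to per-frame ROI means from a bleached region,
a non-bleached reference and the background:

1. subtract the background trace frame-wise from bleached and reference;
2. divide each by its own mean over the 5 frames immediately before the bleach;
3. form the ratio R(t) = bleached / reference — any per-frame multiplicative
   factor common to both channels (acquisition bleaching) cancels here;
4. rescale to full scale, value(t) = (R(t) − R₀) / (1 − R₀) with R₀ the ratio at
   the first post-bleach frame, so the first post-bleach value is exactly 0 and
   full recovery is 1.

The immobile fraction is 1 minus the mean of value(t) over a late window,
50–100 s post-bleach by default (inclusive bounds), where the mobile pool has
plateaued.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CircleRoi, ImageStack, circle_mean

logger = logging.getLogger(__name__)

PRE_BLEACH_NORM_FRAMES = 5
DEFAULT_WINDOW_S = (50.0, 100.0)


@dataclass
class FrapTrace:
    """Raw per-frame ROI means with the bleach frame index.

    ``bleach_frame`` is the index of the first post-bleach frame.
    """

    t_s: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.t_s)
        if not (len(self.bleached) == len(self.reference) == len(self.background) == n):
            raise ValueError("all trace channels must have equal length")
        if self.bleach_frame < PRE_BLEACH_NORM_FRAMES:
            raise ValueError(
                f"need >= {PRE_BLEACH_NORM_FRAMES} pre-bleach frames, "
                f"bleach_frame={self.bleach_frame}"
            )
        if self.bleach_frame >= n:
            raise ValueError("bleach_frame outside trace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "bleached": self.bleached,
                "reference": self.reference,
                "background": self.background,
                "is_postbleach": np.arange(len(self.t_s)) >= self.bleach_frame,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrapTrace":
        post = np.asarray(df["is_postbleach"], dtype=bool)
        if not post.any():
            raise ValueError("trace has no post-bleach frames")
        return cls(
            df["t_s"].to_numpy(),
            df["bleached"].to_numpy(),
            df["reference"].to_numpy(),
            df["background"].to_numpy(),
            int(np.argmax(post)),
        )


@dataclass
class NormalizedFrap:
    """Post-bleach normalized recovery curve on a 0–1 scale."""

    t_post_s: np.ndarray
    value: np.ndarray
    r0: float = 0.0  # ratio at the first post-bleach frame (bleach depth diagnostic)

    def __post_init__(self) -> None:
        self.t_post_s = np.asarray(self.t_post_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.t_post_s) != len(self.value):
            raise ValueError("t_post_s and value must have equal length")


@dataclass
class FrapResult:
    """Immobile fraction (raw; may leave [0,1] slightly under noise) and its window."""

    immobile_fraction: float
    window_s: tuple[float, float] = DEFAULT_WINDOW_S


def extract_frap_traces(
    stack: ImageStack,
    bleached_roi: CircleRoi,
    reference_roi: CircleRoi,
    background_roi: CircleRoi,
    bleach_frame: int,
) -> FrapTrace:
    """Per-frame circular-ROI means for the three FRAP channels.

    Each value is the arithmetic mean of pixels whose centers fall inside the
    circle. Overlap of bleached and reference ROIs is allowed but warned about.
    """
    bx, by = bleached_roi.center
    rx, ry = reference_roi.center
    if np.hypot(bx - rx, by - ry) < (bleached_roi.diameter_px + reference_roi.diameter_px) / 2:
        warnings.warn("bleached and reference ROIs overlap", stacklevel=2)
    t = np.arange(stack.n_frames) * stack.frame_interval_s
    channels = {}
    for name, roi in (
        ("bleached", bleached_roi),
        ("reference", reference_roi),
        ("background", background_roi),
    ):
        channels[name] = np.array([circle_mean(fr, roi) for fr in stack.data])
    return FrapTrace(t, channels["bleached"], channels["reference"],
                     channels["background"], bleach_frame)


def normalize_frap(trace: FrapTrace) -> NormalizedFrap:
    """Apply the double-normalization chain and zero the first post-bleach frame."""
    k = trace.bleach_frame
    pre = slice(k - PRE_BLEACH_NORM_FRAMES, k)

    bleached = trace.bleached - trace.background
    reference = trace.reference - trace.background
    pre_b = bleached[pre].mean()
    pre_r = reference[pre].mean()
    if pre_b <= 0 or pre_r <= 0:
        raise ValueError("non-positive pre-bleach mean after background subtraction")
    ratio = (bleached / pre_b) / (reference / pre_r)

    r0 = ratio[k]
    if r0 >= 1:
        raise ValueError(
            f"no bleach depth: ratio at first post-bleach frame is {r0:.3f} >= 1"
        )
    value = (ratio[k:] - r0) / (1.0 - r0)
    t_post = trace.t_s[k:] - trace.t_s[k]
    return NormalizedFrap(t_post, value, r0=float(r0))


def immobile_fraction(
    norm: NormalizedFrap,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    allow_short: bool = False,
) -> FrapResult:
    """1 − mean normalized recovery over the post-bleach window (inclusive bounds)."""
    lo, hi = window_s
    t_max = norm.t_post_s[-1]
    if t_max < hi:
        if not allow_short:
            raise ValueError(
                f"trace covers only {t_max:.0f} s post-bleach, window ends at {hi:.0f} s"
            )
        logger.warning("short trace: shrinking window [%g, %g] -> [%g, %g]", lo, hi, lo, t_max)
        hi = t_max
        if t_max < lo:
            raise ValueError("trace ends before the averaging window starts")
    in_window = (norm.t_post_s >= lo) & (norm.t_post_s <= hi)
    return FrapResult(float(1.0 - norm.value[in_window].mean()), (lo, hi))


def aggregate_frap(
    curves: list[NormalizedFrap],
    results: list[FrapResult],
    labels: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group mean recovery curves ± SEM and per-animal immobile percentages.

    Curves within a group are linearly resampled onto the first curve's time
    grid when grids differ. Returns (curve_table, fraction_table); SEM is NaN
    for groups of one.
    """
    if not (len(curves) == len(results) == len(labels)):
        raise ValueError("curves, results and labels must align")
    curve_rows = []
    for group in sorted(set(labels)):
        members = [c for c, lab in zip(curves, labels) if lab == group]
        grid = members[0].t_post_s
        stackv = np.vstack(
            [np.interp(grid, c.t_post_s, c.value) if len(c.t_post_s) != len(grid)
             or not np.allclose(c.t_post_s, grid) else c.value for c in members]
        )
        mean = stackv.mean(axis=0)
        if len(members) > 1:
            sem = stackv.std(axis=0, ddof=1) / np.sqrt(len(members))
        else:
            sem = np.full_like(mean, np.nan)
        curve_rows.append(pd.DataFrame(
            {"group": group, "t_post_s": grid, "mean": mean, "sem": sem}
        ))
    fractions = pd.DataFrame(
        {
            "group": labels,
            "immobile_pct": [100.0 * r.immobile_fraction for r in results],
        }
    )
    return pd.concat(curve_rows, ignore_index=True), fractions
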