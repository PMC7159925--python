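"""Synthetic forward models with known ground truth for every assay.

Each generator is a pure function of (scenario, seed) and returns the data
object together with a JSON-serializable ground-truth dict sufficient to score
any downstream estimate without re-simulation. The generators emulate:

* EB-comet movies — plus-end marker comets nucleating as a Poisson process
  along a straight neurite and moving ballistically, rendered as Gaussian
  spots at 1 frame/s;
* FRAP traces — a two-pool (immobile + mobile) bleached-ROI signal with
  mono-exponential mobile recovery, a non-bleached reference, multiplicative
  per-frame acquisition bleaching and a common background;
* photoactivation movies — a marked tubulin segment whose centroid follows a
  prescribed motion pattern along the neurite;
* periodic line profiles — a raised cosine of known period (~190 nm for the
  spectrin-like membrane skeleton) plus Gaussian noise.

The named presets pin the scenarios used for parameter-recovery checks:
``unc33L_frap`` (immobile fraction 0.85), ``unc33MS_frap`` (0.60),
``unc119_frap`` (0.75), ``spectrin_period`` (190 nm), ``strong_slide``
(0.15 µm/s toward the cell body) and ``no_slide``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf

from .core_io import ORIGIN_CB_LOW, ImageStack
from .frap import FrapTrace
from .periodicity import LineProfile


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class CometScenario:
    """EB-comet movie: Poisson nucleation, ballistic motion, Gaussian spots."""

    n_frames: int = 200
    frame_interval_s: float = 1.0
    length_um: float = 15.0
    pixel_size_um: float = 0.110
    fraction_retrograde: float = 0.5
    comet_speed_um_s: tuple[float, float] = (0.22, 0.03)  # (mean, sd)
    nucleation_rate: float = 1.0  # events / (um * min)
    mean_track_duration_s: float = 20.0  # exponential growth-run lifetime
    comet_psf_sigma_px: float = 1.5
    amplitude: float = 60.0
    background: float = 20.0
    noise_sigma: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_retrograde <= 1.0:
            raise ValueError("fraction_retrograde must be in [0, 1]")
        if self.nucleation_rate < 0 or self.comet_speed_um_s[0] < 0:
            raise ValueError("rates and speeds must be >= 0")
        step_um = self.comet_speed_um_s[0] * self.frame_interval_s
        if step_um > self.length_um / 2:
            raise ValueError("comet displacement per frame exceeds half the neurite")


@dataclass
class FrapScenario:
    """Two-pool FRAP trace with acquisition bleaching and Gaussian noise.

    The latent bleached-ROI signal is S0 pre-bleach; the bleach leaves a
    residual fraction of the fluorescence, after which the mobile pool recovers
    mono-exponentially back to full:

        B(t) = residual + (S0 - residual) * (1 - f_imm) * (1 - exp(-t / tau)).

    ``noise_sigma`` is expressed as a fraction of the pre-bleach signal S0.
    """

    immobile_fraction: float = 0.5
    mobile_tau_s: float = 8.0
    n_prebleach_frames: int = 10
    n_postbleach_frames: int = 110
    frame_interval_s: float = 1.0
    acquisition_bleach_per_frame: float = 0.001
    background_level: float = 10.0
    noise_sigma: float = 0.02
    s0: float = 100.0
    bleach_residual_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not self.mobile_tau_s > 0:
            raise ValueError("mobile_tau_s must be > 0")
        if self.n_prebleach_frames < 5:
            raise ValueError("need >= 5 pre-bleach frames for normalization")


@dataclass
class SlidingScenario:
    """Photoactivated-segment movie; drift < 0 means toward the cell body."""

    drift_um_s: float = 0.0
    segment_length_um: float = 3.0
    n_frames: int = 200
    frame_interval_s: float = 1.0
    neurite_length_um: float = 40.0
    pixel_size_um: float = 0.110
    motion_pattern: str = "constant"  # constant | piecewise | bidirectional | stationary
    psf_sigma_px: float = 1.5
    amplitude: float = 60.0
    background: float = 10.0
    noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.motion_pattern not in ("constant", "piecewise", "bidirectional", "stationary"):
            raise ValueError(f"unknown motion_pattern {self.motion_pattern!r}")
        if self.segment_length_um <= 0 or self.neurite_length_um <= 0:
            raise ValueError("lengths must be > 0")


@dataclass
class PeriodScenario:
    """1-D periodic intensity profile sampled from a reconstructed image."""

    true_period_nm: float = 190.0
    profile_length_um: float = 4.0
    sample_spacing_nm: float = 32.5
    amplitude: float = 100.0
    background: float = 20.0
    noise_sigma: float = 20.0
    min_length_um: float = 2.0

    def __post_init__(self) -> None:
        if self.profile_length_um < self.min_length_um:
            raise ValueError("profile shorter than the minimum analysis length")
        if not self.sample_spacing_nm < self.true_period_nm / 2:
            raise ValueError(
                "Nyquist violation: sample spacing must be < half the period"
            )


PRESETS: dict[str, object] = {
    "unc33L_frap": FrapScenario(immobile_fraction=0.85),
    "unc33MS_frap": FrapScenario(immobile_fraction=0.60),
    "unc119_frap": FrapScenario(immobile_fraction=0.75),
    "spectrin_period": PeriodScenario(true_period_nm=190.0),
    "strong_slide": SlidingScenario(drift_um_s=-0.15, motion_pattern="constant"),
    "no_slide": SlidingScenario(drift_um_s=0.0, motion_pattern="stationary"),
}


def get_preset(name: str):
    """Return a fresh copy of a named scenario preset."""
    try:
        return dataclasses.replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


def _scenario_dict(s) -> dict:
    d = dataclasses.asdict(s)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def write_truth(truth: dict, path: str | Path) -> None:
    """Write the ground-truth sidecar JSON next to a generated dataset."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# comet movies
# ---------------------------------------------------------------------------

def generate_comet_movie(s: CometScenario, seed: int = 0) -> tuple[ImageStack, dict]:
    """Render an EB-comet movie on a straight horizontal neurite.

    Comets nucleate as a homogeneous Poisson process in space-time at
    ``nucleation_rate`` events/(µm·min), move ballistically at speeds drawn from
    the stated normal distribution (truncated at 0), retrograde (toward low x,
    i.e. toward the cell body) with probability ``fraction_retrograde``, and
    disappear after an exponential growth-run lifetime or on leaving the
    neurite. Ground truth lists every comet's (t, x) path and direction.
    """
    rng = np.random.default_rng(seed)
    dt = s.frame_interval_s
    px = s.pixel_size_um
    duration_s = s.n_frames * dt
    width_px = int(round(s.length_um / px)) + 1
    height_px = 15
    y0 = height_px // 2

    n_comets = rng.poisson(s.nucleation_rate * s.length_um * duration_s / 60.0)
    t_nuc = rng.uniform(0.0, duration_s, n_comets)
    x_nuc = rng.uniform(0.0, s.length_um, n_comets)
    retro = rng.random(n_comets) < s.fraction_retrograde
    speeds = np.clip(rng.normal(*s.comet_speed_um_s, n_comets), 0.0, None)
    lifetimes = rng.exponential(s.mean_track_duration_s, n_comets)

    frames_t = np.arange(s.n_frames) * dt
    xx = np.arange(width_px)[None, :]
    yy = np.arange(height_px)[:, None]
    stack = np.full((s.n_frames, height_px, width_px), s.background, dtype=float)
    truth_tracks = []
    for i in range(n_comets):
        v = speeds[i] * (-1.0 if retro[i] else 1.0)
        alive = (frames_t >= t_nuc[i]) & (frames_t <= t_nuc[i] + lifetimes[i])
        x_t = x_nuc[i] + v * (frames_t - t_nuc[i])
        alive &= (x_t >= 0.0) & (x_t <= s.length_um)
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            continue
        path = []
        for f in idx:
            cx = x_t[f] / px
            spot = s.amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - y0) ** 2) / (2 * s.comet_psf_sigma_px**2)
            )
            stack[f] += spot
            path.append([float(frames_t[f]), float(x_t[f])])
        truth_tracks.append(
            {
                "t0_s": float(t_nuc[i]),
                "x0_um": float(x_nuc[i]),
                "speed_um_s": float(speeds[i]),
                "direction": "retrograde" if retro[i] else "anterograde",
                "path": path,
            }
        )
    if s.noise_sigma > 0:
        stack += rng.normal(0.0, s.noise_sigma, stack.shape)

    image = ImageStack(stack, px, dt, ORIGIN_CB_LOW)
    truth = {
        "scenario": _scenario_dict(s),
        "seed": seed,
        "n_nucleations": int(n_comets),
        "n_comets": len(truth_tracks),
        "tracks": truth_tracks,
        "neurite_y_px": y0,
    }
    return image, truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def generate_frap_trace(s: FrapScenario, seed: int = 0) -> tuple[FrapTrace, dict]:
    """Simulate the three FRAP ROI channels for one bleach experiment.

    Signal channels are multiplied by cumulative acquisition bleaching
    (1 − b)^frame, the background level is added to all three channels, and
    Gaussian noise (sigma = ``noise_sigma``·S0) is added last.
    """
    rng = np.random.default_rng(seed)
    n = s.n_prebleach_frames + s.n_postbleach_frames
    k = s.n_prebleach_frames
    t = np.arange(n) * s.frame_interval_s
    t_post = t[k:] - t[k]

    residual = s.bleach_residual_frac * s.s0
    bleached = np.full(n, s.s0)
    bleached[k:] = residual + (s.s0 - residual) * (1.0 - s.immobile_fraction) * (
        1.0 - np.exp(-t_post / s.mobile_tau_s)
    )
    reference = np.full(n, s.s0)

    decay = (1.0 - s.acquisition_bleach_per_frame) ** np.arange(n)
    bleached = bleached * decay + s.background_level
    reference = reference * decay + s.background_level
    background = np.full(n, s.background_level)

    if s.noise_sigma > 0:
        sigma = s.noise_sigma * s.s0
        bleached = bleached + rng.normal(0.0, sigma, n)
        reference = reference + rng.normal(0.0, sigma, n)
        background = background + rng.normal(0.0, sigma, n)

    trace = FrapTrace(t, bleached, reference, background, bleach_frame=k)
    truth = {
        "scenario": _scenario_dict(s),
        "seed": seed,
        "immobile_fraction": s.immobile_fraction,
        "bleach_frame": k,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# photoactivation movies
# ---------------------------------------------------------------------------

def _centroid_path(s: SlidingScenario, t: np.ndarray, x0: float) -> np.ndarray:
    v = s.drift_um_s
    if s.motion_pattern == "stationary" or v == 0.0:
        return np.full_like(t, x0)
    if s.motion_pattern == "constant":
        return x0 + v * t
    half = t[-1] / 2.0
    if s.motion_pattern == "piecewise":
        return x0 + v * np.minimum(t, half)
    # bidirectional: +|v| then -|v|
    out = x0 + abs(v) * np.minimum(t, half)
    late = t > half
    out[late] = out[late] - abs(v) * (t[late] - half)
    return out


def generate_photoactivation_movie(
    s: SlidingScenario, seed: int = 0
) -> tuple[ImageStack, dict]:
    """Render a photoactivated tubulin segment translocating along a neurite.

    The segment is a box of ``segment_length_um`` convolved with a Gaussian PSF,
    placed on a horizontal neurite; its centroid follows the scenario's motion
    pattern from frame 0. If the motion would carry the segment out of the field
    of view the path is clamped at the border and the truth records it.
    """
    rng = np.random.default_rng(seed)
    px = s.pixel_size_um
    dt = s.frame_interval_s
    width_px = int(round(s.neurite_length_um / px)) + 1
    height_px = 15
    y0 = height_px // 2
    t = np.arange(s.n_frames) * dt

    half_seg = s.segment_length_um / 2.0
    # start near the end opposite the drift so the segment stays in view
    total_drift = s.drift_um_s * t[-1] if s.motion_pattern == "constant" else 0.0
    x0 = float(np.clip(
        s.neurite_length_um / 2.0 - total_drift / 2.0,
        half_seg + 1.0,
        s.neurite_length_um - half_seg - 1.0,
    ))
    path = _centroid_path(s, t, x0)
    lo, hi = half_seg, s.neurite_length_um - half_seg
    truncated = bool((path < lo).any() or (path > hi).any())
    if truncated:
        warnings.warn("segment reaches the field-of-view border; path clamped",
                      stacklevel=2)
        path = np.clip(path, lo, hi)

    xs_um = np.arange(width_px) * px
    sigma_um = s.psf_sigma_px * px
    yy = np.arange(height_px)[:, None]
    y_prof = np.exp(-((yy - y0) ** 2) / (2 * s.psf_sigma_px**2))
    stack = np.empty((s.n_frames, height_px, width_px), dtype=float)
    for f in range(s.n_frames):
        a, b = path[f] - half_seg, path[f] + half_seg
        seg = 0.5 * (erf((xs_um - a) / (math.sqrt(2) * sigma_um))
                     - erf((xs_um - b) / (math.sqrt(2) * sigma_um)))
        stack[f] = s.background + s.amplitude * y_prof * seg[None, :]
    if s.noise_sigma > 0:
        stack += rng.normal(0.0, s.noise_sigma, stack.shape)

    image = ImageStack(stack, px, dt, ORIGIN_CB_LOW)
    truth = {
        "scenario": _scenario_dict(s),
        "seed": seed,
        "t_s": t.tolist(),
        "centroid_x_um": path.tolist(),
        "truncated": truncated,
        "neurite_y_px": y0,
    }
    return image, truth


# ---------------------------------------------------------------------------
# periodic profiles
# ---------------------------------------------------------------------------

def generate_periodic_profile(
    s: PeriodScenario, seed: int = 0, source_label: str = ""
) -> tuple[LineProfile, dict]:
    """A raised-cosine periodic profile plus Gaussian noise.

    intensity(x) = background + amplitude · (1 + cos(2πx/p)) / 2 + noise.
    """
    rng = np.random.default_rng(seed)
    dx_um = s.sample_spacing_nm / 1000.0
    n = int(round(s.profile_length_um / dx_um)) + 1
    x_um = np.arange(n) * dx_um
    period_um = s.true_period_nm / 1000.0
    intensity = s.background + s.amplitude * (1.0 + np.cos(2 * np.pi * x_um / period_um)) / 2.0
    if s.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, s.noise_sigma, n)
    profile = LineProfile(x_um, intensity, source_label)
    truth = {
        "scenario": _scenario_dict(s),
        "seed": seed,
        "true_period_nm": s.true_period_nm,
    }
    return profile, truth
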