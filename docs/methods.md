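# Methods

This note records the models behind each estimator, the forward models used to
validate them, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Geometry and sampling conventions

Coordinates are 0-based, continuous, `(x, y)` = (column, row); intervals are
half-open. Polyline reslicing samples at exactly 1-pixel arc-length steps with
bilinear interpolation; at each step, `width_px` samples at 1-pixel spacing
perpendicular to the local segment direction are reduced by `max` (default,
which preserves dim comets) or `mean`. Physical box sizes convert to pixels by
rounding each dimension to the nearest integer pixel, so a 120 × 5 µm axon box
at 110 nm/pixel becomes a 1091 × 45 px window. Circular ROI means average the
pixels whose centers fall inside the circle; the conventional "20 pixel round
selection" is read as a **diameter** of 20 px (the common oval-selection
phrasing; radius/area readings would change ROI size, not the normalization
chain, and the diameter is configurable). Calibration (pixel size, frame
interval) always travels in a YAML sidecar; TIFF tags are never trusted.
Pixel-size presets: 0.110 µm (60× objective), 0.067 µm (100×).

## FRAP

**Estimator.** Background-subtracted bleached and reference traces are each
divided by their own mean over the 5 frames before the bleach; the ratio
R(t) = bleached/reference cancels any per-frame factor common to both channels
(the acquisition-bleaching correction — an exact invariance, tested to 1e-9).
"Setting the first post-bleach frame to 0" is implemented as full-scale
normalization, value(t) = (R(t) − R₀)/(1 − R₀): plain subtraction would leave
the pre-bleach level at 1 − R₀ rather than 1, and the immobile fraction
f_imm = 1 − ⟨value⟩ over the 50–100 s post-bleach window (inclusive bounds,
measured from the bleach) is only a 0-to-1 fraction on that scale. The
estimate is reported raw — noise can push it slightly outside [0, 1]; clipping
is presentation only.

**Forward model.** Two pools: an immobile fraction f and a mobile fraction
1 − f that recovers mono-exponentially with time constant τ. The bleach leaves
a residual fraction r (default 0.1) of the fluorescence, and the mobile pool
recovers from its bleached level back to full, so the latent bleached signal
is B(t) = rS₀ + (1 − r)S₀(1 − f)(1 − e^{−t/τ}). With this model the
normalization chain inverts the forward model exactly: value(t) =
(1 − f)(1 − e^{−t/τ}) independent of r, S₀, background and bleaching.
Defaults: τ = 8 s (the mobile pool is ≥ 99.8% recovered at 50 s, so the
window averages a plateau), 10 pre-bleach + 110 post-bleach frames at 1 fps,
acquisition bleaching 0.001/frame, Gaussian noise σ = 0.02·S₀ on all three
channels. Explicit diffusion is not modeled — the estimator only assumes a
plateau in the read-out window, so the recovery shape before ~30 s is
irrelevant to it.

**Exactness.** Noise-free, the estimate equals the closed form
1 − (1 − f)·⟨1 − e^{−t/τ}⟩_window to machine precision; against the scenario
truth f it carries the mobile pool's residual tail, (1 − f)⟨e^{−t/τ}⟩_window
≈ 5·10⁻⁵ at τ = 8 s and up to ~10⁻³ at τ = 10 s. Tests assert both, at their
own scales.

## Kymographs and comet tracking

Row f of the kymograph is the reslice of frame f; dx = pixel size, dt = frame
interval. The track detector is deliberately simple, matched to 1 fps comet
imaging: per-row peaks above median + 5 robust SDs (MAD-based) with sub-pixel
parabolic refinement, greedy nearest-neighbor linking within a 3 px/frame
gate, no gap closing by default (1-frame closing behind a flag). Chains
shorter than 3 s or 0.5 µm are discarded; velocity is the least-squares slope;
|slope| < 0.02 µm/s is "ambiguous" and excluded from polarity counts so sign
noise cannot inflate either class. Retrograde (toward the cell body, resolved
via the kymograph orientation) comets report minus-end-out microtubules.

The comet forward model nucleates comets as a homogeneous Poisson process
(default 1 event/(µm·min) on a 15 µm neurite), draws speeds from
N(0.22, 0.03) µm/s, assigns retrograde direction with probability
`fraction_retrograde`, and ends growth runs after an exponential lifetime
(mean 20 s) or at the neurite end — without finite lifetimes nearly every
comet would cross the full field, which real EB comets do not. Comets are
rendered as Gaussian spots (σ = 1.5 px, amplitude 60 on background 20, noise
SD 4).

Known detector properties, measured against ground truth: the duration/run
filters remove the ~20% of runs shorter than 3 s / 0.5 µm, and crossing
tracks fragment ~8% extra chains at the default density, so detected counts
are compared to the eligibility-matched truth (15% tolerance) rather than raw
nucleation counts; direction estimates are unbiased (polarity fractions
recover the generated mix within 0.1 across the full range); mean velocity
error is ~4% noise-free.

## Photoactivation sliding

The segment is tracked per frame on the neurite line profile (mean reslice):
the median sample is the background, samples above half the background-
subtracted peak form the segment mask, and the centroid is the
intensity-weighted mean arc position. Tracking truncates when the peak falls
below 3× the robust noise — after that frame the marked tubulin is
indistinguishable from background. Events are monotone runs of the 5-frame
moving-average centroid (≤1-frame interruptions allowed) lasting ≥5 s with
net displacement ≥0.5 µm; velocity is net displacement over duration. The
event granularity is this package's definition — the per-animal average and
the 0.1 µm/s strong-sliding cut are the published quantities; the run
definition is validated only against synthetic truth. Animals with no events
contribute mean velocity 0 (never strong), and the strong threshold is a
strict inequality. Flipping the anatomical origin label flips every event's
direction and leaves speeds unchanged (tested).

The forward model renders a 3 µm segment (box ⊗ Gaussian PSF) on a 40 µm
neurite, 200 frames at 1 fps, with constant / piecewise / bidirectional /
stationary centroid motion; paths that would leave the field are clamped at
the border and flagged in the truth. Velocity recovery is within 0.02 µm/s
for drifts of 0.05–0.3 µm/s, and strong/quiet classification is correct in
≥95% of seeds at 0.15 and 0 µm/s.

## Spatial periodicity

Profiles are mean-subtracted and linearly detrended (the low-frequency
envelope of uneven labeling otherwise leaks into the band), zero-padded to
≥8× length, and the dominant frequency is the in-band (100–400 nm) power
maximum refined by quadratic interpolation over the three surrounding bins —
a 4 µm profile has ~12 nm bin spacing near 190 nm after padding, and the
interpolation brings the recovery error to ≤5 nm MAE at 5:1 SNR. The
autocorrelation is biased-normalized (acf(0) = 1); its first off-zero peak is
an independent estimate of the period and agrees with the spectral one within
one sample spacing at SNR ≥ 3.

A peak is only reported when the peak power exceeds 20× the median in-band
power. Under a white-noise null the maximum of the ~30 effectively
independent in-band bins sits at 6–10× the median, so thresholds in the
single digits would pass nearly every noise profile; periodic profiles at
SNR 3 exceed 50×. The 20× default was set from that null simulation and
replaces the visual pre-selection of "neurites showing periodicity".
Minimum profile length defaults to 3 µm, configurable down to 2 µm. The
default sample spacing of reconstructed images is 32.5 nm (well below half
the 170–200 nm structure). The optics helper `fringe_period_nm` gives the
two-beam excitation fringe period λ/(2·NA) — 164 nm for 473 nm at NA 1.44,
i.e. the "~170 nm" illumination pattern of the instrument.

## Statistics

Mid-ranks for ties throughout; Kruskal–Wallis uses the standard tie
correction. Dunn z-statistics use the pooled-rank SE with Bonferroni
adjustment over the k(k−1)/2 pairs; for k = 2 the Dunn z equals the rank-sum
z exactly (tested algebraically). Pairwise rank-sum tests are exact for
combined n ≤ 20 without ties (verified against full enumeration), otherwise
tie-corrected normal. The Nemenyi critical value is computed, not tabulated:
q_c = q(α, k, ∞)/√2 = 2.728 at α = 0.05, k = 5, slightly below the commonly
tabulated 2.8; the computed value is authoritative here and the family-wise
error under a 5-group null is ≤0.07 by simulation. The t-test is
pooled-variance by default with Welch behind a flag.

## What the synthetic data does and does not show

The generators carry the statistical structure each estimator assumes —
Poisson nucleation, ballistic comets, plateaued two-pool recovery, rigid
segment translocation, a single stationary spatial frequency, additive
Gaussian noise — so passing tests demonstrate correct inversion of those
models and correct arithmetic on the published summary definitions. They do
not emulate stage drift (a pre-registration hook exists; no registration is
implemented), comet catastrophe/rescue cycles, photoactivated-tubulin
diffusion halos (modeled optionally, off by default), camera noise beyond
additive Gaussian, curved or branched neurites, or reconstruction artifacts
in superresolved images. Estimates on real movies inherit whatever those
effects add; the pipeline's numbers are exact only for the stated models.

## Problem sizes

Default test and acceptance scenarios are sized for single-CPU runs: 20–25
FRAP replicates per preset, 200–400-frame movies of 15–40 µm neurites, 50–100
seed repeats for recovery statistics and 2000 replicates for the type-I-error
simulation.
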