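# mtanchor

Quantification pipelines for the live-imaging assays used to study how the
neuronal microtubule cytoskeleton is anchored to the cell cortex in
*C. elegans* neurons, where a membrane-associated Ankyrin/UNC-119/CRMP complex
immobilizes axonal and dendritic microtubule bundles and opposes kinesin-1
driven sliding. The package is aimed at cell biologists analyzing time-lapse
fluorescence movies of neurites; every estimator ships with a synthetic
forward model with known ground truth, so the whole pipeline is validated by
parameter recovery without any external data.

Four assays are covered, plus the statistics used to compare groups:

* **Kymograph polarity** (`mtanchor.kymograph`) — EBP-2::GFP comet movies
  (1 frame/s) are resliced along a neurite polyline into a time × position
  kymograph; comet tracks are detected and linked, and the minus-end-out
  fraction is the share of comets growing toward the cell body,
  *f* = n_retro / (n_retro + n_antero).
* **FRAP immobile fraction** (`mtanchor.frap`) — per-frame means of a
  bleached circle, a non-bleached reference and the background are combined
  by double normalization: background subtraction, division by the 5-frame
  pre-bleach mean, the ratio R(t) = bleached/reference to cancel acquisition
  bleaching, and full-scale zeroing at the first post-bleach frame. The
  immobile fraction is f_imm = 1 − ⟨value(t)⟩ for t ∈ [50, 100] s post-bleach.
* **Microtubule sliding** (`mtanchor.sliding`) — a photoactivated
  PA-GFP::tubulin segment is tracked as the intensity-weighted centroid of
  its line profile; monotone centroid runs become sliding events; events are
  averaged per animal, and a mean velocity above 0.1 µm/s classifies the
  animal as *strong sliding*.
* **Membrane-skeleton periodicity** (`mtanchor.periodicity`) — line profiles
  (≥3 µm) from superresolved neurites are Fourier-decomposed; the dominant
  spatial period (the actin/spectrin lattice sits at ~190 nm) is the in-band
  power maximum with quadratic peak interpolation, cross-checked by the first
  autocorrelation peak.
* **Statistics** (`mtanchor.stats`) — Kruskal–Wallis with Dunn's post-hoc,
  pairwise exact rank-sum tests, the unpaired t-test, and the Nemenyi
  post-hoc for unequal sample sizes, whose statistic
  q_ij = |R̄_i − R̄_j| / √(N(N+1)/12 · (1/n_i + 1/n_j)) is compared against
  q_c = q(α, k, ∞)/√2 from the studentized range.

`mtanchor.synthetic` generates the matching synthetic data: comet movies with
Poisson nucleation, two-pool FRAP traces, translocating photoactivated
segments and noisy periodic profiles, each returning a ground-truth sidecar.

## Worked example

Simulate a FRAP experiment with the UNC-33L preset (ground-truth immobile
fraction 0.85, mobile τ = 8 s, 0.1%/frame acquisition bleaching, 2% noise)
and analyze it:

```sh
$ mtanchor simulate --scenario unc33L_frap --seed 1 --out demo
wrote demo/
$ mtanchor frap --trace demo/trace.csv --out demo/frap
immobile fraction: 0.858 (85.8%)
```

The single-trace estimate (85.8%) scatters around the 85% ground truth by a
couple of percentage points at the default noise level; averaging 20
replicates recovers it to well under 1 point. Periodicity works the same way:

```sh
$ mtanchor simulate --scenario spectrin_period --seed 3 --out demo2
$ mtanchor period --profile demo2/profile.csv --out demo2/per
roi 0: period 190.1 nm
```

i.e. the 190 nm lattice period is recovered to 0.1 nm from a 4 µm profile at
5:1 signal-to-noise. The same analyses are available as plain functions:

```python
from mtanchor import frap, synthetic

trace, truth = synthetic.generate_frap_trace(synthetic.get_preset("unc33L_frap"), seed=1)
result = frap.immobile_fraction(frap.normalize_frap(trace))
print(result.immobile_fraction)   # 0.858...
```

## Layout

```
src/mtanchor/
  core_io.py      TIFF/ROI/YAML I/O, polyline reslicing, projections, densities
  synthetic.py    ground-truth forward models and named presets
  kymograph.py    kymographs, comet tracking, polarity & dynamics summaries
  frap.py         FRAP normalization chain and immobile fraction
  sliding.py      segment tracking, sliding events, per-animal classification
  periodicity.py  spectral period, autocorrelation, group collection
  stats.py        rank-based multigroup comparisons
  cli.py          `mtanchor` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
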