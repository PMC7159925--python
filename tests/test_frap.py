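"""FRAP normalization chain, immobile-fraction estimator and group aggregation."""

import dataclasses

import numpy as np
import pytest

from mtanchor import synthetic
from mtanchor.core_io import CircleRoi, ImageStack
from mtanchor.frap import (
    FrapTrace,
    NormalizedFrap,
    aggregate_frap,
    extract_frap_traces,
    immobile_fraction,
    normalize_frap,
)


def _trace(bleached, reference=None, background=None, bleach_frame=5):
    n = len(bleached)
    t = np.arange(n, dtype=float)
    reference = np.full(n, 100.0) if reference is None else np.asarray(reference, float)
    background = np.zeros(n) if background is None else np.asarray(background, float)
    return FrapTrace(t, np.asarray(bleached, float), reference, background, bleach_frame)


def closed_form_estimate(s: synthetic.FrapScenario) -> float:
    """Expected immobile-fraction estimate for a noise-free scenario.

    The normalized recovery is (1 - f)(1 - exp(-t/tau)); averaging over the
    window frames leaves the residual mobile tail as a small positive bias.
    """
    t = np.arange(s.n_postbleach_frames) * s.frame_interval_s
    w = (t >= 50.0) & (t <= 100.0)
    recovery = (1.0 - s.immobile_fraction) * (1.0 - np.exp(-t[w] / s.mobile_tau_s))
    return 1.0 - recovery.mean()


class TestExtractTraces:
    def test_constant_movie_constant_trace(self):
        st = ImageStack(np.full((8, 40, 40), 100.0), 0.11, 1.0)
        tr = extract_frap_traces(st, CircleRoi((10, 10), 8), CircleRoi((30, 30), 8),
                                 CircleRoi((10, 30), 8), bleach_frame=5)
        np.testing.assert_allclose(tr.bleached, 100.0)
        np.testing.assert_allclose(tr.reference, 100.0)

    def test_background_region_reports_its_level(self):
        data = np.full((6, 40, 40), 50.0)
        data[:, 25:, :] = 10.0
        st = ImageStack(data, 0.11, 1.0)
        tr = extract_frap_traces(st, CircleRoi((10, 10), 8), CircleRoi((30, 10), 8),
                                 CircleRoi((20, 33), 8), bleach_frame=5)
        np.testing.assert_allclose(tr.background, 10.0)

    def test_overlapping_rois_warn(self):
        st = ImageStack(np.full((6, 40, 40), 5.0), 0.11, 1.0)
        with pytest.warns(UserWarning, match="overlap"):
            extract_frap_traces(st, CircleRoi((15, 15), 20), CircleRoi((20, 15), 20),
                                CircleRoi((33, 33), 8), bleach_frame=5)


class TestNormalize:
    def test_forced_arithmetic_example(self):
        # pre-bleach 100 with background 10; post-bleach drops to 10 then 55:
        # R0 = 0 and the 50%-recovered frame normalizes to exactly 0.5
        bleached = [100.0] * 5 + [10.0, 55.0]
        bg = [10.0] * 7
        norm = normalize_frap(_trace(bleached, [100.0] * 7, bg, bleach_frame=5))
        assert norm.value[0] == pytest.approx(0.0, abs=1e-12)
        assert norm.value[1] == pytest.approx(0.5, abs=1e-12)

    def test_multiplicative_decay_cancels(self):
        """Per-frame bleaching common to both channels leaves the curve unchanged."""
        n = 60
        base_b = np.array([100.0] * 5 + [20.0 + 1.2 * i for i in range(n - 5)])
        base_r = np.full(n, 100.0)
        plain = normalize_frap(_trace(base_b, base_r))
        decay = 0.999 ** np.arange(n)
        decayed = normalize_frap(_trace(base_b * decay, base_r * decay))
        np.testing.assert_allclose(decayed.value, plain.value, atol=1e-9)

    def test_constant_offset_invariance(self):
        n = 60
        b = np.array([100.0] * 5 + [30.0 + i for i in range(n - 5)])
        r = np.full(n, 100.0)
        bg = np.full(n, 7.0)
        plain = normalize_frap(_trace(b, r, bg))
        shifted = normalize_frap(_trace(b + 13.0, r + 13.0, bg + 13.0))
        np.testing.assert_allclose(shifted.value, plain.value, atol=1e-9)

    def test_no_bleach_depth_rejected(self):
        n = 20
        same = np.full(n, 100.0)
        with pytest.raises(ValueError, match="bleach depth"):
            normalize_frap(_trace(same, same))

    def test_nonpositive_prebleach_rejected(self):
        b = np.array([5.0] * 5 + [1.0] * 10)
        bg = np.full(15, 5.0)
        with pytest.raises(ValueError, match="pre-bleach"):
            normalize_frap(_trace(b, np.full(15, 100.0), bg))


class TestImmobileFraction:
    def _norm(self, value, t=None):
        value = np.asarray(value, float)
        t = np.arange(len(value), dtype=float) if t is None else t
        return NormalizedFrap(t, value)

    def test_window_arithmetic(self):
        norm = self._norm(np.full(120, 0.3))
        assert immobile_fraction(norm).immobile_fraction == pytest.approx(0.70)
        norm = self._norm(np.full(120, 1.0))
        assert immobile_fraction(norm).immobile_fraction == pytest.approx(0.0)

    def test_window_is_inclusive_postbleach_time(self):
        t = np.arange(120, dtype=float)
        value = np.where((t >= 50) & (t <= 100), 0.4, -5.0)
        res = immobile_fraction(self._norm(value, t))
        assert res.immobile_fraction == pytest.approx(0.6)

    def test_short_trace_rejected_unless_allowed(self):
        norm = self._norm(np.full(80, 0.2))
        with pytest.raises(ValueError, match="window"):
            immobile_fraction(norm)
        res = immobile_fraction(norm, allow_short=True)
        assert res.immobile_fraction == pytest.approx(0.8)
        assert res.window_s[1] == 79.0

    @pytest.mark.parametrize("f_imm,tau", [(0.85, 8.0), (0.60, 8.0), (0.0, 5.0),
                                           (1.0, 10.0), (0.75, 10.0)])
    def test_noise_free_estimator_matches_closed_form(self, f_imm, tau):
        """Noise-free pipeline equals the generator closed form to 1e-6 and the
        scenario truth up to the mobile pool's residual tail (< 2e-3 for tau<=10)."""
        s = synthetic.FrapScenario(immobile_fraction=f_imm, mobile_tau_s=tau,
                                   noise_sigma=0.0)
        trace, _ = synthetic.generate_frap_trace(s, seed=0)
        est = immobile_fraction(normalize_frap(trace)).immobile_fraction
        assert est == pytest.approx(closed_form_estimate(s), abs=1e-6)
        assert abs(est - f_imm) <= 2e-3

    def test_recovery_with_default_noise(self):
        s = synthetic.get_preset("unc33L_frap")
        ests = []
        for seed in range(20):
            trace, _ = synthetic.generate_frap_trace(s, seed=seed)
            ests.append(immobile_fraction(normalize_frap(trace)).immobile_fraction)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.85) <= max(2 * sem, 0.01)


class TestAggregate:
    def _curve(self, value):
        return NormalizedFrap(np.arange(len(value), dtype=float), np.asarray(value))

    def test_identical_curves_zero_sem(self):
        from mtanchor.frap import FrapResult

        c = self._curve(np.linspace(0, 0.4, 110))
        curves, fracs = aggregate_frap([c, c], [FrapResult(0.8), FrapResult(0.9)],
                                       ["wt", "wt"])
        np.testing.assert_allclose(curves["sem"], 0.0, atol=1e-12)
        assert fracs["immobile_pct"].mean() == pytest.approx(85.0)

    def test_group_of_one_sem_missing(self):
        from mtanchor.frap import FrapResult

        c = self._curve(np.linspace(0, 0.4, 10))
        curves, _ = aggregate_frap([c], [FrapResult(0.8)], ["solo"])
        assert curves["sem"].isna().all()

    def test_replicate_simulation_recovers_preset(self):
        from mtanchor.frap import FrapResult

        s = synthetic.get_preset("unc33L_frap")
        curves, results, labels = [], [], []
        for seed in range(1, 21):
            trace, _ = synthetic.generate_frap_trace(s, seed=seed)
            norm = normalize_frap(trace)
            curves.append(norm)
            results.append(immobile_fraction(norm))
            labels.append("unc33L")
        _, fracs = aggregate_frap(curves, results, labels)
        vals = fracs["immobile_pct"]
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 85.0) <= 2 * sem + 0.5
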