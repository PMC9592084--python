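"""Transient quantification, exclusion rules, averaging, and statistics."""

import numpy as np
import pytest

from flimphot.traces import (
    AnalysisThresholds,
    ExclusionRecord,
    ROITrace,
    TransientMetrics,
    bin_and_average,
    compare_groups,
    delta_f_over_f,
    peredox_rcamp_ratio,
    summarize_box,
    transient_metrics,
)

THR = AnalysisThresholds()


def _trace(times, values, sensor="SBFI", units="counts", stim=None, roi="r0"):
    return ROITrace(roi, sensor, np.asarray(times, float), np.asarray(values, float),
                    units, stim)


def _metrics(delta, half_decay, polarity="up", baseline=0.88):
    return TransientMetrics(
        baseline=baseline,
        delta_peak=delta,
        time_to_peak_s=1.0,
        half_decay_time_s=half_decay,
        polarity=polarity,
    )


class TestDeltaFOverF:
    def test_constant_trace_maps_to_zero(self):
        t = np.arange(0, 200, 10.0)
        tr = _trace(t, np.full_like(t, 500.0), stim=100.0)
        out = delta_f_over_f(tr)
        assert np.allclose(out.values, 0.0)
        assert out.units == "dF/F"

    def test_quench_magnitude(self):
        # baseline 1000, stimulus-evoked minimum 744 -> dF/F peak -0.256
        t = np.arange(0, 130, 5.0)
        v = np.full_like(t, 1000.0)
        v[t > 100] = 744.0
        out = delta_f_over_f(_trace(t, v, stim=100.0))
        m = transient_metrics(out, polarity="down", thresholds=THR)
        assert m.dff_peak == pytest.approx(-0.256)

    def test_invariant_under_multiplicative_rescaling(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 200, 5.0)
        v = 800 + 50 * rng.standard_normal(t.size)
        a = delta_f_over_f(_trace(t, v, stim=100.0))
        b = delta_f_over_f(_trace(t, 3.7 * v, stim=100.0))
        assert np.allclose(a.values, b.values)

    def test_needs_baseline_samples(self):
        tr = _trace([99.0, 100.0, 101.0, 102.0], [1.0] * 4, stim=100.0)
        with pytest.raises(ValueError, match="baseline"):
            delta_f_over_f(tr)


class TestTransientMetrics:
    def test_exponential_decay_half_life_recovered(self):
        # fast Ca2+-sensor-like transient: t1/2 = 0.41 s sampled at 4 Hz
        pre = np.arange(0, 60, 10.0)
        post = 60.0 + np.arange(0, 20, 0.25)
        t = np.concatenate([pre, post])
        v = np.where(t < 60, 1.0, 1.0 + np.exp(-(t - 60) * np.log(2) / 0.41))
        m = transient_metrics(_trace(t, v, sensor="RCaMP", units="ns", stim=60.0))
        assert m.delta_peak == pytest.approx(1.0, abs=0.01)
        assert m.half_decay_time_s == pytest.approx(0.41, abs=0.05)

    def test_flat_trace_has_zero_peak_and_no_half_decay(self):
        t = np.arange(0, 200, 5.0)
        m = transient_metrics(_trace(t, np.ones_like(t), stim=100.0))
        assert m.delta_peak == 0.0
        assert m.half_decay_time_s is None

    def test_linear_ramp_crosses_halfway_at_ten_seconds(self):
        t = np.concatenate([np.arange(0, 100, 10.0), [100.0], np.arange(101, 125, 1.0)])
        v = np.zeros_like(t)
        post = t >= 100
        v[post] = np.maximum(1.0 - (t[post] - 100.0) / 20.0, 0.0)  # hits 0.5 at t=110
        m = transient_metrics(_trace(t, v, stim=100.0))
        assert m.half_decay_time_s == pytest.approx(10.0, abs=1e-9)

    def test_downward_polarity_takes_minimum(self):
        t = np.arange(0, 150, 5.0)
        v = np.full_like(t, 1000.0)
        v[(t > 100) & (t < 120)] = 700.0
        m = transient_metrics(_trace(t, v, stim=100.0), polarity="down")
        assert m.delta_peak == pytest.approx(-300.0)

    def test_metrics_scale_invariance_of_dff(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 200, 2.0)
        v = 1000 + 100 * np.exp(-((t - 110) / 10) ** 2) + rng.normal(0, 2, t.size)
        m1 = transient_metrics(delta_f_over_f(_trace(t, v, stim=100.0)))
        m2 = transient_metrics(delta_f_over_f(_trace(t, 5 * v, stim=100.0)))
        assert m1.delta_peak == pytest.approx(m2.delta_peak)
        assert m1.half_decay_time_s == pytest.approx(m2.half_decay_time_s)

    def test_stim_outside_span_rejected(self):
        tr = _trace([0.0, 1.0, 2.0], [1, 1, 1])
        with pytest.raises(ValueError, match="span"):
            transient_metrics(tr, stim_time_s=10.0)


class TestPeredoxRCaMPRatio:
    def test_ratio_of_valid_recording(self):
        r = peredox_rcamp_ratio(_metrics(0.024, 20.0), _metrics(0.20, 20.0), THR)
        assert r == pytest.approx(0.12)

    def test_small_rcamp_excluded(self):
        r = peredox_rcamp_ratio(_metrics(0.02, 20.0), _metrics(0.15, 20.0), THR)
        assert isinstance(r, ExclusionRecord)
        assert r.rule == "min_delta_rcamp"

    def test_slow_half_decay_excluded(self):
        r = peredox_rcamp_ratio(_metrics(0.02, 20.0), _metrics(0.5, 40.0), THR)
        assert isinstance(r, ExclusionRecord)
        assert r.rule == "max_half_decay"

    def test_every_pair_yields_exactly_one_outcome(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            rc = _metrics(float(rng.uniform(0, 0.6)),
                          float(rng.uniform(1, 60)) if rng.random() > 0.1 else None)
            px = _metrics(float(rng.uniform(-0.05, 0.2)), 50.0)
            out = peredox_rcamp_ratio(px, rc, THR)
            assert isinstance(out, (float, ExclusionRecord))


class TestBinAndAverage:
    def test_identical_traces_reproduce_with_zero_sd(self):
        t = np.arange(0, 200, 5.0)
        v = np.sin(t / 20.0) + 2.0
        traces = [_trace(t, v, stim=100.0, roi=f"r{i}") for i in range(3)]
        avg = bin_and_average(traces)
        ref = np.interp(avg.common_times_s, t - 100.0, v)
        assert np.allclose(avg.sd, 0.0)
        assert np.allclose(avg.mean, ref, atol=1e-9)

    def test_two_constant_traces_mean_sd_sem(self):
        t = np.arange(0, 200, 10.0)
        a = _trace(t, np.full_like(t, 1.0), stim=100.0, roi="a")
        b = _trace(t, np.full_like(t, 3.0), stim=100.0, roi="b")
        avg = bin_and_average([a, b])
        covered = avg.n_per_point == 2
        assert np.allclose(avg.mean[covered], 2.0)
        assert np.allclose(avg.sd[covered], np.sqrt(2.0))
        assert np.allclose(avg.sem[covered], 1.0)

    def test_cohort_peak_within_sem_of_truth(self):
        # 13 noisy transients with known mean peak amplitude
        rng = np.random.default_rng(7)
        true_peak = -0.25
        traces = []
        t = np.concatenate([np.arange(0, 60, 10.0), 60 + np.arange(0, 60, 1.0)])
        for i in range(13):
            amp = true_peak * (1 + 0.1 * rng.standard_normal())
            v = np.where(t < 62, 0.0, amp * np.exp(-(t - 62) / 25.0))
            v += rng.normal(0, 0.01, t.size)
            traces.append(_trace(t, v, units="dF/F", stim=60.0, roi=f"c{i}"))
        avg = bin_and_average(traces)
        idx = np.argmin(avg.mean)
        assert abs(avg.mean[idx] - true_peak) < 2 * avg.sem[idx] + 0.01

    def test_traces_without_stimulus_rejected(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(ValueError, match="stim_time"):
            bin_and_average([_trace(t, np.ones_like(t)),
                             _trace(t, np.ones_like(t))])


class TestCompareGroups:
    def test_identical_paired_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = compare_groups(a, a, paired=True)
        assert rep.pvalue == 1.0
        assert "paired" in rep.test_name

    def test_gaussian_samples_use_parametric_branch(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 1, 60)
        rep = compare_groups(a, b)
        assert rep.test_name == "two-sample t-test"
        assert rep.pvalue > 0.001

    def test_heavy_tailed_samples_use_nonparametric_branch(self):
        rng = np.random.default_rng(3)
        a = rng.standard_cauchy(50)
        b = rng.normal(0, 1, 50)
        rep = compare_groups(a, b)
        assert rep.test_name == "Mann-Whitney"
        assert not rep.normal_a

    def test_paired_branch_names(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        rep = compare_groups(a, a + rng.normal(0.1, 0.2, 30), paired=True)
        assert rep.test_name in ("paired t-test", "paired Wilcoxon")

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSummarizeBox:
    def test_linear_interpolation_percentiles(self):
        s = summarize_box(np.arange(1.0, 101.0))
        assert s.median == pytest.approx(50.5)
        assert s.p5 == pytest.approx(5.95)
        assert s.p95 == pytest.approx(95.05)

    def test_single_value(self):
        s = summarize_box([3.5])
        assert s.mean == s.median == s.p5 == s.p95 == 3.5

    def test_symmetric_data_mean_equals_median(self):
        v = np.concatenate([np.linspace(-1, 1, 51)])
        s = summarize_box(v)
        assert s.mean == pytest.approx(s.median)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_box([])
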