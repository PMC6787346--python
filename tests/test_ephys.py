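import numpy as np
import pytest

from scmlab.ephys import (
    average_aligned,
    count_spikes,
    detect_events,
    estimate_noise_sd,
    event_metrics,
    fi_curve,
    passive_properties,
    spontaneous_stats,
    summarize_events,
    synaptic_template,
    template_rise_time_10_90_ms,
)
from scmlab.io_formats import EphysTrace
from scmlab.synthetic import (
    CCStepSpec,
    TraceSpec,
    gen_cc_steps,
    gen_passive_step,
    gen_vc_trace,
)

FS = 10_000.0


def _vc(samples):
    return EphysTrace(samples, FS, "voltage_clamp", cell_id="c")


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        assert len(detect_events(_vc(np.zeros(10_000)), 10.0)) == 0

    def test_noise_only_false_positive_rate(self):
        # pure Gaussian noise, 20 seeds: < 0.1 false events/s at 15 pA
        total_events = 0
        total_s = 0.0
        for seed in range(20):
            trace, _ = gen_vc_trace(TraceSpec(duration_s=10, event_rate_hz=0.0,
                                              noise_sd_pa=2.0, seed=seed))
            total_events += len(detect_events(trace, 15.0))
            total_s += trace.duration_s
        assert total_events / total_s < 0.1

    def test_injected_events_recovered_within_1ms(self):
        trace, truth = gen_vc_trace(
            TraceSpec(duration_s=20, event_rate_hz=0.5, amplitude_pa=20,
                      noise_sd_pa=2.0, seed=3)
        )
        onsets = detect_events(trace, 8.0)
        det_t = onsets / FS
        matched = sum(
            np.min(np.abs(det_t - t)) < 1e-3 for t in truth["onset_times_s"]
        )
        assert matched >= 0.9 * truth["n_events"]

    def test_low_threshold_warns(self):
        trace, _ = gen_vc_trace(TraceSpec(duration_s=5, event_rate_hz=0, seed=0))
        with pytest.warns(UserWarning, match="unreliable"):
            detect_events(trace, 1.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_events(
                EphysTrace(np.zeros(0), FS, "voltage_clamp"), 10.0
            )


class TestAverageAndMetrics:
    def test_identical_noiseless_events_average_to_one_event(self):
        template = synaptic_template(2, 8, FS)
        x = np.zeros(100_000)
        onsets = np.array([10_000, 30_000, 50_000, 70_000])
        for o in onsets:
            x[o : o + len(template)] -= 20 * template
        avg = average_aligned(_vc(x), onsets, pre_ms=5, post_ms=40)
        single = average_aligned(_vc(x), onsets[:1], pre_ms=5, post_ms=40)
        np.testing.assert_allclose(avg, single, atol=1e-9)

    def test_jittered_onsets_realign(self):
        rng = np.random.default_rng(8)
        template = synaptic_template(2, 8, FS)
        x = np.zeros(200_000)
        true_onsets = np.arange(10_000, 190_000, 2_000)
        for o in true_onsets:
            x[o : o + len(template)] -= 20 * template
        jittered = true_onsets + rng.integers(-2, 3, len(true_onsets))
        avg = average_aligned(_vc(x), jittered, pre_ms=5, post_ms=40)
        m = event_metrics(avg, FS)
        oracle = template_rise_time_10_90_ms(2, 8)
        assert m.rise_time_10_90_ms == pytest.approx(oracle, rel=0.05)

    def test_ideal_waveform_metrics(self):
        w = -20.0 * synaptic_template(2, 8, FS, 600)
        m = event_metrics(w, FS)
        assert m.amplitude_pa == pytest.approx(20.0, abs=0.2)
        assert m.peak_amplitude_pa < 0
        assert m.decay_tau_ms == pytest.approx(8.0, abs=0.4)
        assert m.rise_time_10_90_ms == pytest.approx(
            template_rise_time_10_90_ms(2, 8), rel=0.05
        )

    def test_step_rise_pure_decay(self):
        t = np.arange(400) / FS * 1000
        w = np.r_[np.zeros(50), -20 * np.exp(-t / 5)]
        m = event_metrics(w, FS)
        assert m.decay_tau_ms == pytest.approx(5.0, abs=0.1)
        assert m.rise_time_10_90_ms <= 2 / FS * 1000  # sampling-limited

    def test_scaling_property(self):
        w = -synaptic_template(2, 8, FS, 600)
        m1 = event_metrics(10 * w, FS)
        m2 = event_metrics(40 * w, FS)
        assert m2.amplitude_pa == pytest.approx(4 * m1.amplitude_pa, rel=1e-6)
        assert m2.rise_time_10_90_ms == pytest.approx(m1.rise_time_10_90_ms, rel=1e-9)
        assert m2.decay_tau_ms == pytest.approx(m1.decay_tau_ms, rel=1e-6)

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError, match="extremum"):
            event_metrics(np.zeros(100), FS)

    def test_no_onsets_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            average_aligned(_vc(np.zeros(1000)), np.array([]))

    def test_summarize_events_frequency(self):
        trace, truth = gen_vc_trace(TraceSpec(duration_s=30, seed=2))
        summary = summarize_events(trace, 8.0)
        assert summary.frequency_hz == pytest.approx(
            summary.n_events / trace.duration_s
        )
        assert summary.n_events > 0


class TestFICurve:
    def test_designed_counts_recovered_exactly(self):
        spec = CCStepSpec(seed=1)
        traces, truth = gen_cc_steps(spec)
        fi = fi_curve(
            traces, spec.step_amplitudes_pa, truth["step_start_s"], truth["step_duration_s"]
        )
        np.testing.assert_array_equal(fi.spike_counts, truth["spike_counts"])

    def test_subthreshold_all_zero(self):
        spec = CCStepSpec(spike_counts=(0,) * 10, seed=0)
        traces, truth = gen_cc_steps(spec)
        fi = fi_curve(
            traces, spec.step_amplitudes_pa, truth["step_start_s"], truth["step_duration_s"]
        )
        assert np.all(fi.spike_counts == 0)

    def test_refractory_merges_close_crossings(self):
        # two upward crossings 0.3 ms apart count once
        v = np.full(5000, -65.0)
        v[1000:1002] = 10.0
        v[1003:1005] = 10.0
        assert count_spikes(v, FS, 0.0, 0.5) == 1

    def test_monotone_safe(self):
        v = np.full(5000, -65.0)
        v[1000:1005] = 10.0
        base = count_spikes(v, FS, 0.0, 0.5)
        v[2000:2005] = 10.0
        assert count_spikes(v, FS, 0.0, 0.5) >= base


class TestSpontaneous:
    def test_periodic_train(self):
        stats = spontaneous_stats(np.arange(0.25, 10, 0.5), 10.0)
        assert stats.rate_hz == pytest.approx(2.0)
        assert stats.cv_isi == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(0)
        isi = rng.exponential(0.2, 500)
        times = np.cumsum(isi)
        stats = spontaneous_stats(times, float(times[-1] + 0.1))
        assert stats.cv_isi == pytest.approx(1.0, abs=0.15)

    def test_two_spikes_cv_missing(self):
        stats = spontaneous_stats([0.5, 1.0], 2.0)
        assert stats.rate_hz == pytest.approx(1.0)
        assert np.isnan(stats.cv_isi)

    def test_time_origin_invariance(self):
        t = np.array([1.0, 1.7, 2.9, 3.4])
        s1 = spontaneous_stats(t, 10.0)
        s2 = spontaneous_stats(t + 100.0, 10.0)
        assert s1.rate_hz == s2.rate_hz
        assert s1.cv_isi == pytest.approx(s2.cv_isi)


class TestPassive:
    def test_noiseless_recovery_to_point1_percent(self):
        trace, truth = gen_passive_step()
        props = passive_properties(trace, -50.0, truth["step_start_s"], truth["step_duration_s"])
        assert props.input_resistance_mohm == pytest.approx(100.0, rel=1e-3)
        assert props.time_constant_ms == pytest.approx(10.0, rel=1e-3)
        assert props.capacitance_pf == pytest.approx(100.0, rel=1e-3)
        assert props.resting_potential_mv == pytest.approx(-70.0, abs=1e-6)

    def test_capacitance_consistency(self):
        trace, truth = gen_passive_step(input_resistance_mohm=150, capacitance_pf=80)
        props = passive_properties(trace, -50.0, truth["step_start_s"], truth["step_duration_s"])
        assert props.capacitance_pf == pytest.approx(
            props.time_constant_ms / props.input_resistance_mohm * 1000, rel=1e-6
        )

    def test_zero_step_rejected(self):
        trace, truth = gen_passive_step()
        with pytest.raises(ValueError, match="deflection"):
            passive_properties(trace, 0.0, truth["step_start_s"], truth["step_duration_s"])


def test_noise_sd_estimator_robust_to_events():
    trace, _ = gen_vc_trace(TraceSpec(duration_s=20, noise_sd_pa=2.0, seed=4))
    assert estimate_noise_sd(trace.samples) == pytest.approx(2.0, rel=0.1)
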