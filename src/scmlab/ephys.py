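"""Patch-clamp trace analytics.

Covers the measurements made on striatal recordings: spontaneous synaptic
event (sEPSC) detection in voltage clamp with rising-phase-aligned averaging
and kinetic metrics (peak amplitude, 10-90% rise time, decay time constant),
spike counting over incremental current steps (F-I curve), spontaneous firing
rate and regularity (CV of interspike intervals), and passive membrane
properties (input resistance, membrane time constant, capacitance) from a
small current step.

Event detection is a transparent threshold-plus-template procedure: candidate
peaks of the baseline-subtracted inward current beyond an amplitude threshold
are kept when their local waveform correlates (Pearson r > 0.5) with a
double-exponential template. All parameters are explicit; commercial
detectors expose the same knobs per cell.

Sign convention: inward synaptic currents are negative; summaries report
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .io_formats import EphysTrace

__all__ = [
    "detect_events",
    "average_aligned",
    "event_metrics",
    "summarize_events",
    "fi_curve",
    "spontaneous_stats",
    "passive_properties",
    "estimate_noise_sd",
    "synaptic_template",
    "template_rise_time_10_90_ms",
]


def synaptic_template(
    tau_rise_ms: float, tau_decay_ms: float, sampling_rate_hz: float, n_samples: int | None = None
) -> np.ndarray:
    """Unit-peak double-exponential synaptic waveform e^(-t/τd) − e^(-t/τr).

    Returned over ``n_samples`` (default: rise-to-peak plus 4 decay
    constants).
    """
    if tau_rise_ms >= tau_decay_ms:
        raise ValueError("tau_rise must be < tau_decay")
    if n_samples is None:
        n_samples = int(round((_t_peak_ms(tau_rise_ms, tau_decay_ms) + 4 * tau_decay_ms)
                              * sampling_rate_hz / 1000))
    t = np.arange(n_samples) / sampling_rate_hz * 1000.0  # ms
    w = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    return w / w.max()


def _t_peak_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time to peak of the double exponential (closed form)."""
    tr, td = tau_rise_ms, tau_decay_ms
    return tr * td / (td - tr) * np.log(td / tr)


def _rising_crossing_ms(tau_rise_ms: float, tau_decay_ms: float, frac: float) -> float:
    """Time (ms) at which the peak-normalized double exponential reaches
    ``frac`` of its peak on the rising limb, by root bisection."""
    tp = _t_peak_ms(tau_rise_ms, tau_decay_ms)
    wp = np.exp(-tp / tau_decay_ms) - np.exp(-tp / tau_rise_ms)

    def g(t: float) -> float:
        return (np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)) / wp - frac

    return optimize.brentq(g, 1e-9, tp)


def template_rise_time_10_90_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Closed-form 10-90% rise time of the double-exponential waveform."""
    return _rising_crossing_ms(tau_rise_ms, tau_decay_ms, 0.9) - _rising_crossing_ms(
        tau_rise_ms, tau_decay_ms, 0.1
    )


def estimate_noise_sd(samples: np.ndarray) -> float:
    """Robust baseline noise SD from the median absolute successive
    difference (insensitive to sparse events)."""
    d = np.diff(np.asarray(samples, dtype=float))
    return float(np.median(np.abs(d - np.median(d))) / 0.6744897501960817 / np.sqrt(2))


def detect_events(
    trace: EphysTrace,
    min_amplitude_pa: float,
    template_rise_ms: float = 2.0,
    template_decay_ms: float = 8.0,
    correlation_threshold: float = 0.5,
) -> np.ndarray:
    """Detect inward synaptic events; returns onset sample indices.

    Candidates are local minima of the lightly smoothed, baseline-subtracted
    current that cross ``-min_amplitude_pa``; a candidate is accepted when
    the raw waveform from its estimated onset correlates with the
    double-exponential template above ``correlation_threshold``. Accepted
    events are spaced at least (template_rise + template_decay) ms apart.
    """
    if len(trace.samples) == 0:
        raise ValueError("empty trace")
    if trace.mode != "voltage_clamp":
        raise ValueError("event detection requires a voltage-clamp trace")
    fs = trace.sampling_rate_hz
    noise_sd = estimate_noise_sd(trace.samples)
    import warnings as _warnings

    if min_amplitude_pa <= 2 * noise_sd:
        _warnings.warn(
            f"min_amplitude ({min_amplitude_pa:g} pA) <= 2x baseline noise SD "
            f"({noise_sd:g} pA): detection unreliable",
            stacklevel=2,
        )
    x = trace.samples - np.median(trace.samples)
    # 0.5 ms boxcar knocks down single-sample noise without blunting a 2 ms rise
    k = max(int(round(0.5e-3 * fs)), 1)
    xs = np.convolve(x, np.ones(k) / k, mode="same")

    refractory = int(round((template_rise_ms + template_decay_ms) * fs / 1000))
    # hysteresis segmentation: trigger when the smoothed current drops below
    # -min_amplitude, release only once it recovers past half the threshold,
    # so noise ripples during an event's decay cannot re-trigger. Within a
    # region, overlapping events appear as separate prominent minima.
    thr = min_amplitude_pa
    trig = np.nonzero((xs[1:] <= -thr) & (xs[:-1] > -thr))[0] + 1
    if xs[0] <= -thr:
        trig = np.r_[0, trig]
    if len(trig) == 0:
        return np.array([], dtype=int)
    recovered = np.nonzero(xs > -0.5 * thr)[0]
    peaks: list[int] = []
    last_end = -1
    for t0 in trig:
        if t0 <= last_end:
            continue
        j = np.searchsorted(recovered, t0)
        end = recovered[j] if j < len(recovered) else len(xs)
        seg = xs[t0 : end + 1]
        local, _ = signal.find_peaks(
            -seg, height=thr, prominence=0.8 * thr, distance=max(refractory, 1)
        )
        if len(local) == 0:
            local = np.array([int(np.argmin(seg))])
        peaks.extend(int(t0 + i) for i in local)
        last_end = end

    peaks.sort()
    t_peak_ms = _t_peak_ms(template_rise_ms, template_decay_ms)
    t_peak_samp = int(round(t_peak_ms * fs / 1000))
    t_half_samp = _rising_crossing_ms(template_rise_ms, template_decay_ms, 0.5) * fs / 1000
    # correlate over rise + 2 decay constants; longer windows swallow the
    # next event when events arrive close together
    corr_len = int(round((t_peak_ms + 2 * template_decay_ms) * fs / 1000))
    template = synaptic_template(template_rise_ms, template_decay_ms, fs, corr_len)

    onsets: list[int] = []
    for k, p in enumerate(peaks):
        # onset from the half-amplitude crossing of the rising limb: the limb
        # is steep there, so localization is far less noise-sensitive than
        # the (flat) peak position
        level = 0.5 * xs[p]
        i = p
        lim = max(p - 3 * t_peak_samp, 1)
        while i > lim and xs[i - 1] <= level:
            i -= 1
        if i > lim and xs[i] != xs[i - 1]:
            frac = (level - xs[i - 1]) / (xs[i] - xs[i - 1])
            onset = int(round(i - 1 + frac - t_half_samp))
        else:
            onset = p - t_peak_samp
        if onset < 0:
            continue
        if onsets and onset - onsets[-1] < refractory:
            continue
        stop = len(x)
        if k + 1 < len(peaks):
            stop = min(stop, peaks[k + 1] - t_peak_samp)
        stop = min(stop, onset + corr_len)
        if stop - onset < max(t_peak_samp, 4):
            continue
        window = x[onset:stop]
        r = np.corrcoef(window, -template[: len(window)])[0, 1]
        if np.isfinite(r) and r > correlation_threshold:
            onsets.append(onset)
    return np.asarray(onsets, dtype=int)


def average_aligned(
    trace: EphysTrace,
    onsets: np.ndarray,
    pre_ms: float = 5.0,
    post_ms: float = 40.0,
    max_jitter_ms: float = 2.0,
) -> np.ndarray:
    """Average event waveform aligned on the rising phase, baseline
    -subtracted.

    Two passes: windows of [-pre_ms, +post_ms] around each onset are first
    averaged as-is; each window is then shifted (within ±max_jitter_ms) to
    maximize the overlap of its rising phase with that first-pass average,
    and re-averaged. In the noiseless limit this pins every event at the
    steepest point of its rise; with noise it is far more stable than
    per-event slope maxima. Baselines are the mean of the earliest 40% of
    each pre-window. Windows running past the trace ends are dropped with a
    warning.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) == 0:
        raise ValueError("need at least one onset to average")
    fs = trace.sampling_rate_hz
    pre = int(round(pre_ms * fs / 1000))
    post = int(round(post_ms * fs / 1000))
    margin = max(int(round(max_jitter_ms * fs / 1000)), 1)
    x = trace.samples.astype(float)

    raw = []
    dropped = 0
    for onset in onsets:
        lo, hi = onset - pre - margin, onset + post + margin
        if lo < 0 or hi > len(x):
            dropped += 1
            continue
        w = x[lo:hi].copy()
        w -= w[margin : margin + max(int(0.4 * pre), 1)].mean()
        raw.append(w)
    if dropped:
        import warnings as _warnings

        _warnings.warn(f"dropped {dropped} event window(s) at trace edges", stacklevel=2)
    if not raw:
        raise ValueError("no complete event windows to average")
    raw = np.asarray(raw)

    core = slice(margin, margin + pre + post)
    ref = raw[:, core].mean(axis=0)
    if len(raw) == 1:
        return ref
    # rising phase + early decay drives the alignment
    a0 = pre - int(round(1e-3 * fs))
    a1 = pre + int(round(12e-3 * fs))
    a0, a1 = max(a0, 0), min(a1, pre + post)
    seg = ref[a0:a1] - ref[a0:a1].mean()

    seg_norm = np.linalg.norm(seg)
    aligned = np.empty_like(raw[:, core])
    lags = np.arange(-margin, margin + 1)
    for i, w in enumerate(raw):
        scores = []
        for l in lags:
            s = w[margin + a0 + l : margin + a1 + l]
            s = s - s.mean()
            denom = np.linalg.norm(s) * seg_norm
            scores.append(np.dot(s, seg) / denom if denom > 0 else -np.inf)
        best = lags[int(np.argmax(scores))]
        aligned[i] = w[margin + best : margin + best + pre + post]
    return aligned.mean(axis=0)


@dataclass(frozen=True)
class EventMetrics:
    peak_amplitude_pa: float  # signed; inward events negative
    amplitude_pa: float  # magnitude
    rise_time_10_90_ms: float
    decay_tau_ms: float


def event_metrics(avg_waveform: np.ndarray, sampling_rate_hz: float) -> EventMetrics:
    """Peak amplitude, 10-90% rise time and decay time constant of an
    averaged event.

    Amplitude is the dominant extremum relative to the (already subtracted)
    baseline. Rise time spans the 10% and 90% amplitude crossings on the
    rising limb, linearly interpolated between samples. The decay time
    constant comes from a least-squares single-exponential fit over the
    falling limb from 80% of peak until the waveform first returns to 10% of
    peak (see the fit-window note above the fit).
    """
    w = np.asarray(avg_waveform, dtype=float)
    fs = sampling_rate_hz
    ipeak = int(np.argmax(np.abs(w)))
    peak = w[ipeak]
    if peak == 0:
        raise ValueError("no event extremum: waveform is flat")
    polarity = np.sign(peak)
    m = w * polarity  # magnitude-oriented, peak positive
    amp = m[ipeak]

    t10 = _crossing_before(m, ipeak, 0.1 * amp, fs)
    t90 = _crossing_before(m, ipeak, 0.9 * amp, fs)
    if t10 is None or t90 is None:
        raise ValueError("non-monotonic rising limb: cannot locate unique 10/90% crossings")

    # decay window: 80% of peak -> first return to 10% of peak. Starting
    # below the peak keeps the residual rising component (which has not yet
    # died at the peak itself) out of the single-exponential fit.
    fall = m[ipeak:]
    below80 = np.nonzero(fall <= 0.8 * amp)[0]
    start = ipeak + (below80[0] if len(below80) else 0)
    below = np.nonzero(m[start:] <= 0.1 * amp)[0]
    end = start + (below[0] if len(below) else len(m) - start)
    tail = m[start:end]
    if len(tail) < 4:
        raise ValueError("decay phase too short to fit")
    t = np.arange(len(tail)) / fs * 1000.0
    # log-linear seed, then nonlinear least squares
    pos = tail > 0
    slope0, intercept0 = np.polyfit(t[pos], np.log(tail[pos]), 1)
    tau0 = -1.0 / slope0 if slope0 < 0 else 10.0

    def expdecay(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            expdecay, t, tail, p0=[float(np.exp(intercept0)), float(abs(tau0))], maxfev=5000
        )
        tau = float(abs(popt[1]))
    except RuntimeError:
        tau = float(abs(tau0))

    return EventMetrics(
        peak_amplitude_pa=float(peak),
        amplitude_pa=float(amp),
        rise_time_10_90_ms=float(t90 - t10),
        decay_tau_ms=tau,
    )


def _crossing_before(m: np.ndarray, ipeak: int, level: float, fs: float) -> float | None:
    """Time (ms) of the last upward crossing of ``level`` before the peak,
    linearly interpolated; None when the limb never drops below the level."""
    for i in range(ipeak, 0, -1):
        if m[i - 1] < level <= m[i]:
            frac = (level - m[i - 1]) / (m[i] - m[i - 1])
            return (i - 1 + frac) / fs * 1000.0
    return None


@dataclass(frozen=True)
class EventSummary:
    """Per-cell sEPSC summary; kinetic values come from the averaged event."""

    cell_id: str
    n_events: int
    frequency_hz: float
    mean_amplitude_pa: float
    rise_time_10_90_ms: float
    decay_tau_ms: float


def summarize_events(
    trace: EphysTrace,
    min_amplitude_pa: float,
    template_rise_ms: float = 2.0,
    template_decay_ms: float = 8.0,
) -> EventSummary:
    """Detect, align, average and measure sEPSCs in one pass."""
    onsets = detect_events(trace, min_amplitude_pa, template_rise_ms, template_decay_ms)
    if len(onsets) == 0:
        return EventSummary(trace.cell_id, 0, 0.0, np.nan, np.nan, np.nan)
    avg = average_aligned(trace, onsets)
    metrics = event_metrics(avg, trace.sampling_rate_hz)
    return EventSummary(
        cell_id=trace.cell_id,
        n_events=len(onsets),
        frequency_hz=len(onsets) / trace.duration_s,
        mean_amplitude_pa=metrics.amplitude_pa,
        rise_time_10_90_ms=metrics.rise_time_10_90_ms,
        decay_tau_ms=metrics.decay_tau_ms,
    )


# ---------------------------------------------------------------------------
# current-clamp analyses


@dataclass(frozen=True)
class FICurve:
    cell_id: str
    step_amplitudes_pa: np.ndarray
    spike_counts: np.ndarray
    step_duration_ms: float = 300.0


def fi_curve(
    traces: list[EphysTrace],
    step_amplitudes_pa: np.ndarray | list[float],
    step_start_s: float,
    step_duration_s: float = 0.3,
    spike_threshold_mv: float = 0.0,
    refractory_ms: float = 1.0,
    clip_limit_mv: float = 80.0,
) -> FICurve:
    """Spike counts per incremental current step (default 50 pA / 300 ms
    protocol).

    A spike is an upward crossing of ``spike_threshold_mv`` within the step
    window; crossings closer than ``refractory_ms`` count once. Saturated
    traces (samples at or beyond ``clip_limit_mv``) are flagged with a
    warning.
    """
    amps = np.asarray(step_amplitudes_pa, dtype=float)
    if len(traces) != len(amps):
        raise ValueError("one trace per step amplitude required")
    counts = []
    for tr in traces:
        if tr.mode != "current_clamp":
            raise ValueError("F-I analysis requires current-clamp traces")
        if np.any(np.abs(tr.samples) >= clip_limit_mv):
            import warnings as _warnings

            _warnings.warn(f"trace {tr.cell_id!r} may be clipped", stacklevel=2)
        counts.append(
            count_spikes(
                tr.samples,
                tr.sampling_rate_hz,
                step_start_s,
                step_duration_s,
                spike_threshold_mv,
                refractory_ms,
            )
        )
    return FICurve(
        cell_id=traces[0].cell_id,
        step_amplitudes_pa=amps,
        spike_counts=np.asarray(counts, dtype=int),
        step_duration_ms=step_duration_s * 1000,
    )


def count_spikes(
    samples: np.ndarray,
    fs: float,
    window_start_s: float,
    window_duration_s: float,
    threshold_mv: float = 0.0,
    refractory_ms: float = 1.0,
) -> int:
    lo = int(round(window_start_s * fs))
    hi = min(int(round((window_start_s + window_duration_s) * fs)), len(samples))
    seg = np.asarray(samples[lo:hi], dtype=float)
    above = seg >= threshold_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if len(crossings) == 0:
        return 0
    refr = refractory_ms * fs / 1000.0
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(c)
    return len(kept)


@dataclass(frozen=True)
class SpontaneousFiring:
    cell_id: str
    n_spikes: int
    rate_hz: float
    cv_isi: float  # NaN when fewer than 3 spikes


def spontaneous_stats(
    spike_times_s: np.ndarray | list[float], duration_s: float, cell_id: str = ""
) -> SpontaneousFiring:
    """Firing rate and interspike-interval coefficient of variation.

    CV(ISI) = SD(ISI)/mean(ISI): 0 for clock-like firing, 1 for a Poisson
    train. Undefined (NaN) with fewer than 3 spikes.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(spike_times_s, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    rate = len(t) / duration_s
    if len(t) >= 3:
        isi = np.diff(t)
        cv = float(np.std(isi, ddof=1) / np.mean(isi))
    else:
        cv = float("nan")
    return SpontaneousFiring(cell_id=cell_id, n_spikes=len(t), rate_hz=rate, cv_isi=cv)


# ---------------------------------------------------------------------------
# passive membrane properties


@dataclass(frozen=True)
class PassiveProperties:
    cell_id: str
    input_resistance_mohm: float
    time_constant_ms: float
    capacitance_pf: float
    resting_potential_mv: float


def passive_properties(
    step_response: EphysTrace,
    step_pa: float,
    step_start_s: float,
    step_duration_s: float,
) -> PassiveProperties:
    """Input resistance, membrane time constant and capacitance from a small
    current step.

    R = ΔV_ss/ΔI from the settled tail of the step; τ from a single
    -exponential fit of the charging phase; C = τ/R. The response must settle
    (final 10% of the step flat to within the fitted τ's prediction).
    """
    if step_pa == 0:
        raise ValueError("no deflection: step amplitude is zero")
    fs = step_response.sampling_rate_hz
    v = step_response.samples
    i0 = int(round(step_start_s * fs))
    i1 = int(round((step_start_s + step_duration_s) * fs))
    if i0 < 1 or i1 > len(v):
        raise ValueError("step window outside trace")
    v_rest = float(np.mean(v[: i0]))
    tail = v[i0 + int(0.8 * (i1 - i0)) : i1]
    v_ss = float(np.mean(tail))
    dv = v_ss - v_rest
    if abs(dv) < 1e-9:
        raise ValueError("no deflection: steady-state voltage change is zero")

    charging = v[i0:i1].astype(float)
    t = np.arange(len(charging)) / fs * 1000.0  # ms

    def model(tt, tau):
        return v_ss + (v_rest - v_ss) * np.exp(-tt / tau)

    # seed from the 63% crossing
    frac = (charging - v_rest) / dv
    idx63 = np.nonzero(frac >= 0.632)[0]
    tau0 = t[idx63[0]] if len(idx63) else (step_duration_s * 1000 / 5)
    popt, _ = optimize.curve_fit(model, t, charging, p0=[max(tau0, t[1])], maxfev=5000)
    tau_ms = float(abs(popt[0]))
    if tau_ms > step_duration_s * 1000 / 3:
        raise ValueError("response does not settle within the step")

    r_mohm = abs(dv) / abs(step_pa) * 1000.0  # mV/pA = GΩ → MΩ
    c_pf = tau_ms / r_mohm * 1000.0  # ms/MΩ = nF → pF
    return PassiveProperties(
        cell_id=step_response.cell_id,
        input_resistance_mohm=r_mohm,
        time_constant_ms=tau_ms,
        capacitance_pf=c_pf,
        resting_potential_mv=v_rest,
    )
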