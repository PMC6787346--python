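"""Ground-truth synthetic data for every pipeline input.

Stands in for the in-vivo recordings the analyses were designed around
(none of which are publicly deposited): T1-weighted phantom cohorts with
ROI-confined group effects and scan-to-scan global intensity variation,
12 LD open-field and wheel-running activity with hour-dependent wake
probability, and voltage-/current-clamp traces with known event and spike
parameters. All generators are pure functions of (spec, seed): reruns are
bit-identical, and every output passes the validators in
:mod:`scmlab.io_formats` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import ActivityTable, EphysTrace, IntensityVolume, LabelAtlas

__all__ = [
    "PhantomSpec",
    "default_phantom_spec",
    "gen_phantom_cohort",
    "ActimetrySpec",
    "default_actimetry_spec",
    "gen_actimetry",
    "gen_open_field",
    "gen_wheel",
    "gen_phase_totals",
    "TraceSpec",
    "gen_vc_trace",
    "CCStepSpec",
    "gen_cc_steps",
    "gen_passive_step",
]

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


# ---------------------------------------------------------------------------
# MEMRI phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort of 3D phantoms: Gaussian baseline, ROI-confined additive group
    shifts (in baseline-SD units), and a per-scan global multiplicative
    intensity factor emulating scan-to-scan variation independent of the
    contrast agent."""

    shape: tuple[int, int, int] = (32, 32, 32)
    roi_boxes: Mapping[str, Box] = field(default_factory=dict)
    baseline_mean: float = 1000.0
    baseline_sd: float = 50.0
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    groups: tuple[str, str] = ("KO", "WT")
    n_subjects_per_group: int = 8
    global_variation: float = 0.10  # per-scan multiplicative factor U(1±this)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ValueError("need >= 2 subjects per group")
        occupied = np.zeros(self.shape, dtype=bool)
        for name, box in self.roi_boxes.items():
            sl = tuple(slice(lo, hi) for lo, hi in box)
            for (lo, hi), dim in zip(box, self.shape):
                if not (0 <= lo < hi <= dim):
                    raise ValueError(f"ROI {name!r} box outside phantom shape")
            if occupied[sl].any():
                raise ValueError(f"ROI {name!r} overlaps another ROI")
            occupied[sl] = True
        for (group, roi) in self.group_effects:
            if group not in self.groups:
                raise ValueError(f"effect group {group!r} not in {self.groups}")
            if roi not in self.roi_boxes:
                raise ValueError(f"effect ROI {roi!r} has no box")


def default_phantom_spec(
    effect_roi: str = "Cpu",
    effect_sd: float = 1.5,
    n_subjects_per_group: int = 8,
    seed: int = 0,
) -> PhantomSpec:
    """Default 32³ phantom with the seven basal-ganglia/septal ROIs used in
    the activity-mapping figures and a shift (default +1.5 SD) confined to
    the caudate-putamen of the first group.

    The effect ROI occupies ~1.3% of the brain mask so that an ROI-confined
    shift barely perturbs the whole-brain normalization statistics; a much
    larger effect fraction couples the z-values of effect-free ROIs to the
    effect (the per-scan mean/SD absorb part of the shift)."""
    boxes: dict[str, Box] = {
        "Cpu": ((4, 11), (4, 11), (4, 11)),
        "AcbC": ((16, 20), (4, 8), (4, 8)),
        "AcbSh": ((16, 20), (12, 16), (4, 8)),
        "GP": ((16, 20), (20, 24), (4, 8)),
        "LS": ((4, 8), (16, 20), (16, 20)),
        "MS": ((12, 16), (16, 20), (16, 20)),
        "BNST": ((20, 26), (16, 20), (16, 20)),
    }
    effects = {("KO", effect_roi): effect_sd} if effect_sd else {}
    return PhantomSpec(
        roi_boxes=boxes,
        group_effects=effects,
        n_subjects_per_group=n_subjects_per_group,
        seed=seed,
    )


def gen_phantom_cohort(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[list[IntensityVolume], np.ndarray, LabelAtlas, dict]:
    """Generate per-subject volumes, a brain mask, the label atlas, and a
    truth record naming the effect-bearing ROIs."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = np.zeros(spec.shape, dtype=bool)
    margin = 1
    mask[margin:-margin, margin:-margin, margin:-margin] = True

    labels = np.zeros(spec.shape, dtype=np.int64)
    names: dict[int, str] = {}
    for i, (name, box) in enumerate(sorted(spec.roi_boxes.items()), start=1):
        sl = tuple(slice(lo, hi) for lo, hi in box)
        labels[sl] = i
        names[i] = name
    atlas = LabelAtlas(labels=labels, names=names)

    volumes = []
    for group in spec.groups:
        for s in range(spec.n_subjects_per_group):
            data = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.shape)
            for (g, roi), shift_sd in spec.group_effects.items():
                if g == group:
                    sl = tuple(slice(lo, hi) for lo, hi in spec.roi_boxes[roi])
                    data[sl] += shift_sd * spec.baseline_sd
            gain = 1.0 + spec.global_variation * rng.uniform(-1, 1)
            data = np.clip(data * gain, 0, None)
            volumes.append(
                IntensityVolume(
                    data=data,
                    voxel_size_mm=np.array([0.1, 0.1, 0.1]),
                    subject_id=f"{group}_{s+1:02d}",
                    group_label=group,
                )
            )
    truth = {
        "effect_rois": sorted({roi for (_, roi) in spec.group_effects}),
        "group_effects": {f"{g}:{r}": v for (g, r), v in spec.group_effects.items()},
        "groups": list(spec.groups),
    }
    return volumes, mask, atlas, truth


# ---------------------------------------------------------------------------
# actimetry


@dataclass(frozen=True)
class ActimetrySpec:
    """12 LD activity cohort with hour-dependent wake probability.

    Open field: each 15-min bin is awake with p_wake(genotype, hour); awake
    bins draw a log-normal distance (cm), sleeping bins are exactly 0.
    Wheel running: negative-binomial revolution counts per 5-min bin with an
    hour-dependent mean (variance = mu + dispersion*mu²).
    """

    n_animals: Mapping[str, int] = field(default_factory=lambda: {"control": 10, "mutant": 10})
    days: int = 5
    p_wake_by_hour: Mapping[tuple[str, int], float] = field(default_factory=dict)
    wake_distance_log_mean: float = np.log(300.0)  # cm per awake 15-min bin
    wake_distance_log_sd: float = 0.5
    wheel_rate_by_hour: Mapping[tuple[str, int], float] = field(default_factory=dict)
    dispersion: float = 0.3
    start: str = "2023-01-01 00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        for (_, _), p in self.p_wake_by_hour.items():
            if not (0 <= p <= 1):
                raise ValueError("wake probabilities must lie in [0, 1]")
        for (_, _), r in self.wheel_rate_by_hour.items():
            if r < 0:
                raise ValueError("wheel rates must be >= 0")


def default_actimetry_spec(
    p_wake_dark: float = 0.95,
    p_wake_light: Mapping[str, float] | None = None,
    wheel_dark: float = 150.0,
    wheel_light: Mapping[str, float] | None = None,
    n_animals: Mapping[str, int] | None = None,
    days: int = 5,
    seed: int = 0,
) -> ActimetrySpec:
    """Designed cohort: dark-phase wake probability 0.95 for everyone; light
    -phase 0.55 (control) vs 0.75 (mutant); wheel running concentrated in the
    dark phase (lights on 06:00-18:00)."""
    p_wake_light = p_wake_light or {"control": 0.55, "mutant": 0.75}
    wheel_light = wheel_light or {"control": 5.0, "mutant": 5.0}
    n_animals = n_animals or {"control": 10, "mutant": 10}
    p_wake = {}
    wheel = {}
    for g in n_animals:
        for h in range(24):
            light = 6 <= h < 18
            p_wake[(g, h)] = p_wake_light[g] if light else p_wake_dark
            wheel[(g, h)] = wheel_light[g] if light else wheel_dark
    return ActimetrySpec(
        n_animals=n_animals,
        days=days,
        p_wake_by_hour=p_wake,
        wheel_rate_by_hour=wheel,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion*mu² (gamma-Poisson
    mixture; collapses to Poisson as dispersion -> 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def gen_open_field(spec: ActimetrySpec, seed: int | None = None) -> ActivityTable:
    """15-min open-field distance table (cm) over ``spec.days`` days."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    start = pd.Timestamp(spec.start)
    n_bins = spec.days * 96
    times = start + pd.to_timedelta(np.arange(n_bins) * 15, unit="m")
    hours = times.hour
    rows = []
    for genotype, n in spec.n_animals.items():
        p = np.array([spec.p_wake_by_hour.get((genotype, h), 0.5) for h in hours])
        for a in range(n):
            awake = rng.uniform(size=n_bins) < p
            dist = np.where(
                awake,
                rng.lognormal(spec.wake_distance_log_mean, spec.wake_distance_log_sd, n_bins),
                0.0,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": f"{genotype}_{a+1:02d}",
                        "genotype": genotype,
                        "bin_start": times,
                        "bin_width_min": 15,
                        "value": dist,
                    }
                )
            )
    return ActivityTable(pd.concat(rows, ignore_index=True))


def gen_wheel(spec: ActimetrySpec, seed: int | None = None) -> ActivityTable:
    """5-min wheel revolution-count table over ``spec.days`` days."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    start = pd.Timestamp(spec.start)
    n_bins = spec.days * 288
    times = start + pd.to_timedelta(np.arange(n_bins) * 5, unit="m")
    hours = times.hour
    rows = []
    for genotype, n in spec.n_animals.items():
        mu = np.array([spec.wheel_rate_by_hour.get((genotype, h), 0.0) for h in hours])
        for a in range(n):
            counts = _nb_draw(rng, mu, spec.dispersion)
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": f"{genotype}_{a+1:02d}",
                        "genotype": genotype,
                        "bin_start": times,
                        "bin_width_min": 5,
                        "value": counts.astype(float),
                    }
                )
            )
    return ActivityTable(pd.concat(rows, ignore_index=True))


@dataclass(frozen=True)
class ActimetryData:
    open_field: ActivityTable
    wheel: ActivityTable
    truth: dict


def gen_actimetry(spec: ActimetrySpec, seed: int | None = None) -> ActimetryData:
    """Both activity modalities plus the generating truth record."""
    base = spec.seed if seed is None else seed
    truth = {
        "p_wake_by_hour": {f"{g}:{h}": p for (g, h), p in spec.p_wake_by_hour.items()},
        "wheel_rate_by_hour": {f"{g}:{h}": r for (g, h), r in spec.wheel_rate_by_hour.items()},
    }
    return ActimetryData(
        open_field=gen_open_field(spec, base),
        wheel=gen_wheel(spec, base + 1),
        truth=truth,
    )


def gen_phase_totals(
    n_control: int,
    n_mutant: int,
    mean_control: float,
    rate_ratio: float,
    dispersion: float,
    n_periods: int = 4,
    seed: int = 0,
    genotypes: tuple[str, str] = ("control", "mutant"),
    family: str = "negative_binomial",
) -> pd.DataFrame:
    """Per-animal, per-period phase totals with a known genotype rate ratio —
    the direct input for regression recovery and calibration studies.

    family "negative_binomial": counts with Var = mu + dispersion*mu²;
    family "gamma": continuous totals with shape 1/dispersion (squared CV =
    dispersion).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, n, mu in (
        (genotypes[0], n_control, mean_control),
        (genotypes[1], n_mutant, mean_control * rate_ratio),
    ):
        for a in range(n):
            if family == "negative_binomial":
                totals = _nb_draw(rng, np.full(n_periods, mu), dispersion)
            elif family == "gamma":
                shape = 1.0 / dispersion
                totals = rng.gamma(shape, mu / shape, n_periods)
            else:
                raise ValueError(f"unknown family {family!r}")
            for p, tot in enumerate(totals, start=1):
                rows.append(
                    {
                        "animal_id": f"{genotype}_{a+1:02d}",
                        "genotype": genotype,
                        "phase": "light",
                        "period_index": p,
                        "total": float(tot),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# electrophysiology traces


@dataclass(frozen=True)
class TraceSpec:
    """Voltage-clamp trace: Poisson synaptic events, each a peak-normalized
    double exponential (inward, negative), over Gaussian noise."""

    duration_s: float = 60.0
    sampling_rate_hz: float = 10_000.0
    event_rate_hz: float = 5.0
    amplitude_pa: float = 20.0
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 8.0
    noise_sd_pa: float = 2.0
    amplitude_cv: float = 0.0  # optional event-to-event amplitude spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise must be < tau_decay")
        if self.event_rate_hz < 0:
            raise ValueError("event rate must be >= 0")


def gen_vc_trace(spec: TraceSpec, seed: int | None = None) -> tuple[EphysTrace, dict]:
    """Synthetic sEPSC trace plus truth (onset times and kinetics)."""
    from .ephys import synaptic_template

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    x = rng.normal(0.0, spec.noise_sd_pa, n)
    n_events = rng.poisson(spec.event_rate_hz * spec.duration_s)
    onsets = np.sort(rng.uniform(0, spec.duration_s, n_events))
    template = synaptic_template(spec.tau_rise_ms, spec.tau_decay_ms, spec.sampling_rate_hz)
    amps = np.full(n_events, spec.amplitude_pa)
    if spec.amplitude_cv > 0:
        amps = amps * rng.lognormal(0, spec.amplitude_cv, n_events)
    kept_onsets = []
    kept_amps = []
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * spec.sampling_rate_hz))
        i1 = min(i0 + len(template), n)
        if i1 <= i0:
            continue
        x[i0:i1] -= a * template[: i1 - i0]
        kept_onsets.append(i0 / spec.sampling_rate_hz)
        kept_amps.append(float(a))
    trace = EphysTrace(
        samples=x,
        sampling_rate_hz=spec.sampling_rate_hz,
        mode="voltage_clamp",
        cell_id=f"vc_seed{spec.seed if seed is None else seed}",
    )
    truth = {
        "onset_times_s": np.asarray(kept_onsets),
        "amplitudes_pa": np.asarray(kept_amps),
        "tau_rise_ms": spec.tau_rise_ms,
        "tau_decay_ms": spec.tau_decay_ms,
        "n_events": len(kept_onsets),
    }
    return trace, truth


@dataclass(frozen=True)
class CCStepSpec:
    """Current-clamp incremental step protocol with an RC subthreshold
    response and stereotyped inserted spikes; spike counts per step are part
    of the spec, so recovery is exact by construction."""

    step_amplitudes_pa: tuple[float, ...] = tuple(50.0 * (i + 1) for i in range(10))
    spike_counts: tuple[int, ...] = (0, 0, 1, 2, 4, 6, 8, 10, 12, 14)
    step_duration_ms: float = 300.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    sampling_rate_hz: float = 10_000.0
    baseline_mv: float = -65.0
    input_resistance_mohm: float = 100.0
    time_constant_ms: float = 10.0
    spike_peak_mv: float = 30.0
    spike_width_ms: float = 2.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.spike_counts) != len(self.step_amplitudes_pa):
            raise ValueError("spike_counts must match step_amplitudes_pa in length")


def gen_cc_steps(spec: CCStepSpec, seed: int | None = None) -> tuple[list[EphysTrace], dict]:
    """One current-clamp trace per step plus true spike counts/times."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.sampling_rate_hz
    n_pre = int(round(spec.pre_ms * fs / 1000))
    n_step = int(round(spec.step_duration_ms * fs / 1000))
    n_post = int(round(spec.post_ms * fs / 1000))
    n = n_pre + n_step + n_post
    t_step = np.arange(n_step) / fs * 1000.0  # ms

    half_w = int(round(spec.spike_width_ms / 2 * fs / 1000))
    traces = []
    true_counts = []
    spike_times_all = []
    for k, (amp, n_spikes) in enumerate(zip(spec.step_amplitudes_pa, spec.spike_counts)):
        v = np.full(n, spec.baseline_mv)
        dv = spec.input_resistance_mohm * amp * 1e-3  # pA·MΩ = µV → mV
        v[n_pre : n_pre + n_step] += dv * (1 - np.exp(-t_step / spec.time_constant_ms))
        v[n_pre + n_step :] = spec.baseline_mv + dv * np.exp(
            -(np.arange(n_post) / fs * 1000.0) / spec.time_constant_ms
        )
        times = []
        if n_spikes > 0:
            # evenly spaced within the step, away from the edges
            centers = n_pre + ((np.arange(n_spikes) + 1) / (n_spikes + 1) * n_step).astype(int)
            for c in centers:
                lo, hi = c - half_w, c + half_w
                tri = spec.spike_peak_mv - v[c]
                prof = tri * (1 - np.abs(np.arange(lo, hi) - c) / half_w)
                v[lo:hi] += np.clip(prof, 0, None)
                times.append(c / fs)
        if spec.noise_sd_mv > 0:
            v = v + rng.normal(0, spec.noise_sd_mv, n)
        traces.append(
            EphysTrace(
                samples=v, sampling_rate_hz=fs, mode="current_clamp",
                cell_id=f"cc_step{k}",
            )
        )
        true_counts.append(n_spikes)
        spike_times_all.append(times)
    truth = {
        "spike_counts": np.asarray(true_counts),
        "spike_times_s": spike_times_all,
        "step_start_s": spec.pre_ms / 1000.0,
        "step_duration_s": spec.step_duration_ms / 1000.0,
    }
    return traces, truth


def gen_passive_step(
    input_resistance_mohm: float = 100.0,
    capacitance_pf: float = 100.0,
    step_pa: float = -50.0,
    baseline_mv: float = -70.0,
    pre_ms: float = 100.0,
    step_duration_ms: float = 300.0,
    post_ms: float = 100.0,
    sampling_rate_hz: float = 10_000.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> tuple[EphysTrace, dict]:
    """RC charging response to a small (default hyperpolarizing) current
    step; truth record carries R, τ = RC, and C."""
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    tau_ms = input_resistance_mohm * capacitance_pf / 1000.0  # MΩ·pF = µs → ms
    n_pre = int(round(pre_ms * fs / 1000))
    n_step = int(round(step_duration_ms * fs / 1000))
    n_post = int(round(post_ms * fs / 1000))
    dv = input_resistance_mohm * step_pa * 1e-3  # mV
    t_step = np.arange(n_step) / fs * 1000.0
    v = np.full(n_pre + n_step + n_post, baseline_mv)
    v[n_pre : n_pre + n_step] += dv * (1 - np.exp(-t_step / tau_ms))
    v[n_pre + n_step :] = baseline_mv + dv * np.exp(
        -(np.arange(n_post) / fs * 1000.0) / tau_ms
    )
    if noise_sd_mv > 0:
        v = v + rng.normal(0, noise_sd_mv, len(v))
    trace = EphysTrace(samples=v, sampling_rate_hz=fs, mode="current_clamp", cell_id="passive")
    truth = {
        "input_resistance_mohm": input_resistance_mohm,
        "time_constant_ms": tau_ms,
        "capacitance_pf": capacitance_pf,
        "step_start_s": pre_ms / 1000.0,
        "step_duration_s": step_duration_ms / 1000.0,
        "resting_potential_mv": baseline_mv,
    }
    return trace, truth
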