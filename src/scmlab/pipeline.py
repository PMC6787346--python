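"""End-to-end pipeline orchestration: synthesize inputs, run each analysis
arm, and write tidy result CSVs plus a reproducibility manifest.

Every run is a pure function of its configuration: identical config (and
seed) produces byte-identical result CSVs. The manifest records the config,
its hash, package version and SHA-256 of each output, so a rerun can be
verified file by file; only the manifest's timestamp differs between reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .actimetry import (
    PhaseConfig,
    code_sleep,
    fit_phase_effect,
    hourly_wheel_profile,
    split_phases,
    waking_probability,
)
from .ephys import fi_curve, passive_properties, summarize_events, estimate_noise_sd
from .memri import compare_all_rois, count_cohort, normalize_zmap
from .synthetic import (
    CCStepSpec,
    TraceSpec,
    default_actimetry_spec,
    default_phantom_spec,
    gen_actimetry,
    gen_cc_steps,
    gen_passive_step,
    gen_phantom_cohort,
    gen_vc_trace,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_memri_pipeline",
    "run_behavior_pipeline",
    "run_ephys_pipeline",
    "run_all",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results"
    # MEMRI arm
    z_threshold: float = 1.0
    divisor_convention: str = "sd"
    fdr: bool = False
    n_subjects_per_group: int = 8
    effect_roi: str = "Cpu"
    effect_sd: float = 1.5
    # behavior arm
    lights_on: int = 6
    lights_off: int = 18
    last_n_days: int = 4
    reference_genotype: str = "control"
    reference_hour: int = 18
    # ephys arm
    min_amplitude_pa: float | None = None  # None → 3x estimated noise SD
    template_rise_ms: float = 2.0
    template_decay_ms: float = 8.0

    def validate(self) -> None:
        if self.divisor_convention not in ("sd", "variance"):
            raise ValueError("divisor_convention must be 'sd' or 'variance'")
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be >= 0")
        if not (0 <= self.reference_hour < 24):
            raise ValueError("reference_hour must be in [0, 24)")

    @property
    def phase_config(self) -> PhaseConfig:
        return PhaseConfig(lights_on=self.lights_on, lights_off=self.lights_off)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, outdir: Path, outputs: list[Path], stage: str) -> Path:
    manifest = {
        "stage": stage,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def run_memri_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Phantom cohort → z-maps → per-ROI counts → group comparisons."""
    config.validate()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = default_phantom_spec(
        effect_roi=config.effect_roi,
        effect_sd=config.effect_sd,
        n_subjects_per_group=config.n_subjects_per_group,
        seed=config.seed,
    )
    volumes, mask, atlas, truth = gen_phantom_cohort(spec)
    zmaps = [normalize_zmap(v, mask, config.divisor_convention) for v in volumes]
    counts = count_cohort(zmaps, atlas, config.z_threshold)
    comparisons = compare_all_rois(counts, *spec.groups, fdr=config.fdr)

    counts_path = outdir / "memri_counts.csv"
    comp_path = outdir / "memri_comparisons.csv"
    counts.to_csv(counts_path, index=False)
    comparisons.to_csv(comp_path, index=False)
    _write_manifest(config, outdir, [counts_path, comp_path], "memri")
    return {"counts": counts, "comparisons": comparisons, "truth": truth}


def run_behavior_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Actimetry cohort → phase totals, sleep series, waking probabilities,
    hourly wheel profile, and phase-level GEE fits."""
    config.validate()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.phase_config
    data = gen_actimetry(default_actimetry_spec(seed=config.seed))

    phases = split_phases(data.open_field, cfg, config.last_n_days)
    sleep = code_sleep(data.open_field, cfg, config.last_n_days)
    pwake = waking_probability(sleep, config.reference_genotype, config.reference_hour)
    wheel = hourly_wheel_profile(data.wheel, cfg, config.last_n_days * 24)

    light = phases[phases["phase"] == "light"]
    gamma_fit = fit_phase_effect(
        light, family="gamma", reference_genotype=config.reference_genotype
    )
    wheel_light = split_phases(data.wheel, cfg, config.last_n_days)
    wheel_light = wheel_light[wheel_light["phase"] == "light"]
    nb_fit = fit_phase_effect(
        wheel_light, family="negative_binomial",
        reference_genotype=config.reference_genotype,
    )

    outputs = []
    for name, df in (
        ("phase_summary.csv", phases),
        ("sleep_series.csv", sleep.assign(bin_start=sleep["bin_start"].astype(str))),
        ("pwake.csv", pwake.table),
        ("pwake_hourly_contrasts.csv", pwake.hourly_contrasts),
        ("wheel_hourly_profile.csv", wheel.profile),
        ("wheel_hourly_tests.csv", wheel.hourly_tests),
    ):
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(path)
    fits = {
        "light_phase_distance_gamma": asdict(gamma_fit),
        "light_phase_wheel_negative_binomial": asdict(nb_fit),
    }
    fits_path = outdir / "behavior_fits.json"
    fits_path.write_text(json.dumps(fits, indent=2, default=str) + "\n")
    outputs.append(fits_path)
    _write_manifest(config, outdir, outputs, "behavior")
    return {
        "phases": phases,
        "sleep": sleep,
        "pwake": pwake,
        "wheel": wheel,
        "fits": {"gamma": gamma_fit, "negative_binomial": nb_fit},
        "truth": data.truth,
    }


def run_ephys_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Synthetic traces → sEPSC summary, F-I curve, passive properties."""
    config.validate()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    vc_trace, vc_truth = gen_vc_trace(TraceSpec(seed=config.seed))
    min_amp = config.min_amplitude_pa
    if min_amp is None:
        min_amp = 3.0 * estimate_noise_sd(vc_trace.samples)
    summary = summarize_events(
        vc_trace, min_amp, config.template_rise_ms, config.template_decay_ms
    )

    cc_traces, cc_truth = gen_cc_steps(CCStepSpec(seed=config.seed))
    fi = fi_curve(
        cc_traces,
        CCStepSpec().step_amplitudes_pa,
        step_start_s=cc_truth["step_start_s"],
        step_duration_s=cc_truth["step_duration_s"],
    )

    step_trace, step_truth = gen_passive_step(seed=config.seed)
    passive = passive_properties(
        step_trace, -50.0, step_truth["step_start_s"], step_truth["step_duration_s"]
    )

    events_df = pd.DataFrame([asdict(summary)])
    fi_df = pd.DataFrame(
        {"step_pa": fi.step_amplitudes_pa, "spike_count": fi.spike_counts}
    )
    passive_df = pd.DataFrame([asdict(passive)])
    outputs = []
    for name, df in (
        ("ephys_events.csv", events_df),
        ("ephys_fi.csv", fi_df),
        ("ephys_passive.csv", passive_df),
    ):
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(path)
    _write_manifest(config, outdir, outputs, "ephys")
    return {
        "events": summary,
        "fi": fi,
        "passive": passive,
        "truth": {"vc": vc_truth, "cc": cc_truth, "passive": step_truth},
    }


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    return {
        "memri": run_memri_pipeline(config, outdir),
        "behavior": run_behavior_pipeline(config, outdir),
        "ephys": run_ephys_pipeline(config, outdir),
    }
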