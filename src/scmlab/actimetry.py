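"""Circadian actimetry: phase-resolved activity, sleep/wake scoring, hourly
wheel-running profiles, and probability-of-waking analysis.

Mice are housed on a 12 h light / 12 h dark (12 LD) cycle and rest during the
light phase. Analyses use the final days of recording: activity is split into
light and dark phases, 15-min open-field bins with zero distance are scored
as sleep, wheel revolutions are summed per clock hour, and the hourly
probability of waking is expressed relative to the control genotype at a
reference hour (the last hour of the light phase, 6 P.M.).

Group effects are estimated with marginal generalized-linear models fitted by
generalized estimating equations (GEE): log-link gamma for continuous phase
totals, log-link negative binomial for wheel counts, logit-link binomial for
the waking indicator, with an exchangeable working correlation over repeated
measures (periods and samples) within animal. Small-sample inference uses the
Mancl–DeRouen bias-reduced sandwich covariance with a t reference whose
degrees of freedom are (number of animals - number of coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_formats import ActivityTable, FormatError

__all__ = [
    "PhaseConfig",
    "select_last_days",
    "split_phases",
    "code_sleep",
    "hourly_wheel_profile",
    "waking_probability",
    "fit_phase_effect",
    "adjust_fdr_by",
]


@dataclass(frozen=True)
class PhaseConfig:
    """Light-cycle configuration: lights on at 06:00, off at 18:00 by default."""

    lights_on: int = 6
    lights_off: int = 18

    def __post_init__(self) -> None:
        for h in (self.lights_on, self.lights_off):
            if not (0 <= h < 24):
                raise ValueError("lights_on/lights_off must be hours in [0, 24)")
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    def is_light(self, hour: int) -> bool:
        if self.lights_on < self.lights_off:
            return self.lights_on <= hour < self.lights_off
        return hour >= self.lights_on or hour < self.lights_off

    @property
    def hours_light(self) -> int:
        return (self.lights_off - self.lights_on) % 24


def _phase_of(hours: pd.Series, cfg: PhaseConfig) -> pd.Series:
    light = hours.map(cfg.is_light)
    return light.map({True: "light", False: "dark"})


def select_last_days(
    table: ActivityTable,
    cfg: PhaseConfig = PhaseConfig(),
    last_n_days: int = 4,
) -> pd.DataFrame:
    """Keep the final ``last_n_days`` complete 24 h periods of a recording.

    The window ends at the last complete lights-off boundary, so each retained
    24 h period contains one full dark phase followed by one full light phase.
    Adds ``period_index`` (1..last_n_days) and ``hour_of_day`` columns.
    Partial leading days are dropped; a table spanning less than the window
    is an error.
    """
    df = table.frame.copy()
    width = pd.Timedelta(minutes=table.bin_width_min)
    last_end = (df["bin_start"] + width).max()
    boundary = last_end.normalize() + pd.Timedelta(hours=cfg.lights_off)
    if boundary > last_end:
        boundary -= pd.Timedelta(days=1)
    start = boundary - pd.Timedelta(days=last_n_days)
    if df["bin_start"].min() > start:
        raise ValueError(
            f"table spans less than {last_n_days} days before the last "
            f"lights-off boundary ({boundary})"
        )
    keep = (df["bin_start"] >= start) & (df["bin_start"] + width <= boundary)
    out = df.loc[keep].copy()
    out["period_index"] = (
        ((out["bin_start"] - start) // pd.Timedelta(days=1)).astype(int) + 1
    )
    out["hour_of_day"] = out["bin_start"].dt.hour
    return out.reset_index(drop=True)


def split_phases(
    table: ActivityTable,
    cfg: PhaseConfig = PhaseConfig(),
    last_n_days: int = 4,
) -> pd.DataFrame:
    """Total activity per animal, phase and period over the final days.

    Each bin is assigned to the light or dark phase by its start time; totals
    are exact sums of member bins (light period k is "day k", dark period k is
    "night k").
    """
    df = select_last_days(table, cfg, last_n_days)
    df["phase"] = _phase_of(df["hour_of_day"], cfg)
    out = (
        df.groupby(["animal_id", "genotype", "phase", "period_index"], as_index=False)[
            "value"
        ]
        .sum()
        .rename(columns={"value": "total"})
    )
    return out.sort_values(["animal_id", "phase", "period_index"]).reset_index(drop=True)


def code_sleep(
    table: ActivityTable,
    cfg: PhaseConfig = PhaseConfig(),
    last_n_days: int | None = None,
) -> pd.DataFrame:
    """Score 15-min open-field bins as sleep (0) or wake (1).

    A bin with exactly zero distance is sleep; any nonzero distance, however
    small, is wake. ``sample_index`` is the bin's ordinal within its clock
    hour (1-4); ``period_index`` is the recording day (within the final
    ``last_n_days`` window when given, otherwise counted from the first bin).
    """
    if table.bin_width_min != 15:
        raise FormatError("sleep coding requires 15-min bins")
    if last_n_days is not None:
        df = select_last_days(table, cfg, last_n_days)
    else:
        df = table.frame.copy()
        t0 = df["bin_start"].min().normalize()
        df["period_index"] = ((df["bin_start"] - t0) // pd.Timedelta(days=1)).astype(int) + 1
        df["hour_of_day"] = df["bin_start"].dt.hour
    df["awake"] = (df["value"] != 0).astype(int)
    df["sample_index"] = df["bin_start"].dt.minute // 15 + 1
    cols = [
        "animal_id",
        "genotype",
        "bin_start",
        "hour_of_day",
        "sample_index",
        "period_index",
        "awake",
    ]
    return df[cols].reset_index(drop=True)


@dataclass
class HourlyWheelProfile:
    """Per-genotype hourly wheel-running means and per-hour group tests."""

    profile: pd.DataFrame  # genotype, hour_of_day, mean, se, n_animals
    hourly_tests: pd.DataFrame  # hour_of_day, t_statistic, p_value
    animal_hour_sums: pd.DataFrame  # animal_id, genotype, hour_of_day, period_index, hourly_sum


def hourly_wheel_profile(
    table: ActivityTable,
    cfg: PhaseConfig = PhaseConfig(),
    last_n_hours: int = 96,
) -> HourlyWheelProfile:
    """Hourly wheel-running profile over the final ``last_n_hours`` hours.

    The twelve 5-min revolution counts in each clock hour are summed per
    animal, giving last_n_hours/24 data points per animal per hour of day.
    The genotype profile is the mean of those points; each hour of day is
    compared between the two genotypes with an unpaired two-tailed t-test on
    per-animal means.
    """
    if table.bin_width_min != 5:
        raise FormatError("hourly wheel profile requires 5-min bins")
    if last_n_hours % 24:
        raise ValueError("last_n_hours must be a whole number of days")
    df = select_last_days(table, cfg, last_n_hours // 24)
    sums = (
        df.groupby(
            ["animal_id", "genotype", "period_index", "hour_of_day"], as_index=False
        )["value"]
        .sum()
        .rename(columns={"value": "hourly_sum"})
    )
    per_animal = (
        sums.groupby(["animal_id", "genotype", "hour_of_day"], as_index=False)[
            "hourly_sum"
        ]
        .mean()
        .rename(columns={"hourly_sum": "animal_mean"})
    )
    profile = (
        sums.groupby(["genotype", "hour_of_day"])
        .agg(
            mean=("hourly_sum", "mean"),
            n_points=("hourly_sum", "size"),
        )
        .reset_index()
    )
    se = (
        per_animal.groupby(["genotype", "hour_of_day"])["animal_mean"]
        .agg(["sem", "size"])
        .reset_index()
        .rename(columns={"sem": "se", "size": "n_animals"})
    )
    profile = profile.merge(se, on=["genotype", "hour_of_day"])

    genotypes = sorted(df["genotype"].unique())
    tests = []
    if len(genotypes) == 2:
        ga, gb = genotypes
        for hour, sub in per_animal.groupby("hour_of_day"):
            xa = sub.loc[sub["genotype"] == ga, "animal_mean"]
            xb = sub.loc[sub["genotype"] == gb, "animal_mean"]
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=True)
            tests.append({"hour_of_day": hour, "t_statistic": float(t), "p_value": float(p)})
    hourly_tests = pd.DataFrame(tests)
    return HourlyWheelProfile(profile=profile, hourly_tests=hourly_tests, animal_hour_sums=sums)


# ---------------------------------------------------------------------------
# GEE fits


@dataclass(frozen=True)
class PhaseEffectResult:
    """Marginal genotype effect from a GEE fit.

    ``effect`` is on the linear-predictor scale (log rate ratio for gamma and
    negative-binomial families, log odds ratio for binomial) relative to the
    reference genotype, which is normalized to 0.
    """

    effect: float
    se: float
    p_value: float
    family: str
    reference_genotype: str
    comparison_genotype: str
    n_animals: int
    df: int
    covariates_used: tuple[str, ...] = ()


def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments dispersion for Var(y) = mu + alpha*mu^2."""
    resid = ((y - mu) ** 2 - y) / mu**2
    alpha = float(np.sum(resid)) / max(len(y) - n_params, 1)
    return max(alpha, 1e-8)


def fit_phase_effect(
    summary: pd.DataFrame,
    family: str,
    response_col: str = "total",
    reference_genotype: str | None = None,
    animal_col: str = "animal_id",
    genotype_col: str = "genotype",
) -> PhaseEffectResult:
    """GEE fit of a response on genotype with repeated measures within animal.

    family: "gamma" (log link, continuous positive totals),
    "negative_binomial" (log link, counts), or "binomial" (logit link,
    0/1 outcomes). Age and sex columns, when present, enter as covariates;
    otherwise they are omitted with a warning. The working correlation is
    exchangeable within animal.
    """
    df = summary.copy()
    genotypes = sorted(df[genotype_col].unique())
    if len(genotypes) != 2:
        raise ValueError(f"need exactly 2 genotypes, got {genotypes}")
    if reference_genotype is None:
        reference_genotype = genotypes[0]
    elif reference_genotype not in genotypes:
        raise ValueError(f"reference genotype {reference_genotype!r} not in data")
    other = [g for g in genotypes if g != reference_genotype][0]

    counts = df.groupby(genotype_col)[animal_col].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 animals per genotype")

    y = df[response_col].to_numpy(dtype=float)
    if family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma family requires strictly positive responses")
    if family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial family requires 0/1 responses")

    df = df.reset_index(drop=True)
    exog = pd.DataFrame({"intercept": np.ones(len(df))})
    exog["genotype_effect"] = (df[genotype_col] == other).to_numpy(dtype=float)
    used = []
    for cov in ("age", "sex", "gender"):
        if cov in df.columns:
            vals = df[cov]
            if vals.dtype == object:
                vals = pd.factorize(vals)[0].astype(float)
            exog[cov] = np.asarray(vals, dtype=float)
            used.append(cov)
    if not used:
        warnings.warn("no age/sex covariate columns present; fitting genotype only",
                      stacklevel=2)

    groups = df[animal_col].to_numpy()
    n_animals = df[animal_col].nunique()

    if family == "gamma":
        fam = sm.families.Gamma(link=sm.families.links.Log())
    elif family == "binomial":
        fam = sm.families.Binomial()
    elif family == "negative_binomial":
        # dispersion from a Poisson working fit, then refit with NB variance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GEE(y, exog, groups=groups, family=sm.families.Poisson(),
                          cov_struct=sm.cov_struct.Exchangeable()).fit()
        alpha = _estimate_nb_alpha(y, pois.fittedvalues, exog.shape[1])
        fam = sm.families.NegativeBinomial(alpha=alpha)
    else:
        raise ValueError(f"unknown family {family!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, exog, groups=groups, family=fam,
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit(cov_type="bias_reduced")

    idx = list(exog.columns).index("genotype_effect")
    beta = float(res.params[idx])
    se = float(res.bse[idx])
    dof = max(n_animals - exog.shape[1], 1)
    if se == 0:
        p = 1.0 if beta == 0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(beta / se), dof))
    return PhaseEffectResult(
        effect=beta,
        se=se,
        p_value=p,
        family=family,
        reference_genotype=reference_genotype,
        comparison_genotype=other,
        n_animals=n_animals,
        df=dof,
        covariates_used=tuple(used),
    )


# ---------------------------------------------------------------------------
# probability of waking


@dataclass
class WakingProbabilityResult:
    """Hour-resolved waking probabilities and genotype contrasts.

    ``table`` has one row per (genotype, hour_of_day) with the empirical
    waking probability (mean of per-animal proportions), its between-animal
    SE, the number of binary observations, and the probability relative to
    the reference genotype at the reference hour. ``hourly_contrasts`` holds
    the per-hour genotype comparison from a binomial GEE.
    """

    table: pd.DataFrame
    hourly_contrasts: pd.DataFrame
    reference_genotype: str
    reference_hour: int
    reference_p_wake: float


def waking_probability(
    series: pd.DataFrame,
    reference_genotype: str,
    reference_hour: int = 18,
) -> WakingProbabilityResult:
    """Estimate hourly waking probability per genotype, normalized to the
    reference genotype's probability at the reference hour (set to 1).

    ``series`` is the output of :func:`code_sleep`. The animal is the
    repeated-measures unit: p_wake(g, h) is the mean over animals of each
    animal's fraction of awake 15-min bins in that clock hour (period 1-4 ×
    sample 1-4). Each hour's genotype contrast is a logit-link binomial GEE
    clustered by animal.
    """
    df = series.copy()
    if reference_genotype not in set(df["genotype"]):
        raise ValueError(f"reference genotype {reference_genotype!r} not in series")
    per_animal = (
        df.groupby(["genotype", "animal_id", "hour_of_day"], as_index=False)["awake"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "p_animal", "size": "n_obs"})
    )
    table = (
        per_animal.groupby(["genotype", "hour_of_day"], as_index=False)
        .agg(
            p_wake=("p_animal", "mean"),
            se=("p_animal", "sem"),
            n_obs=("n_obs", "sum"),
            n_animals=("p_animal", "size"),
        )
    )
    ref_rows = table[
        (table["genotype"] == reference_genotype)
        & (table["hour_of_day"] == reference_hour)
    ]
    if ref_rows.empty:
        raise ValueError(f"no data at reference hour {reference_hour}")
    p_ref = float(ref_rows["p_wake"].iloc[0])
    if p_ref == 0:
        raise ValueError("degenerate reference hour: reference waking probability is 0")
    table["relative_p_wake"] = table["p_wake"] / p_ref

    genotypes = sorted(df["genotype"].unique())
    contrasts = []
    if len(genotypes) == 2:
        for hour, sub in df.groupby("hour_of_day"):
            contrasts.append(
                {"hour_of_day": hour, "p_value": _binary_contrast(sub, reference_genotype)}
            )
    hourly = pd.DataFrame(contrasts)
    return WakingProbabilityResult(
        table=table.sort_values(["genotype", "hour_of_day"]).reset_index(drop=True),
        hourly_contrasts=hourly,
        reference_genotype=reference_genotype,
        reference_hour=reference_hour,
        reference_p_wake=p_ref,
    )


def _binary_contrast(sub: pd.DataFrame, reference_genotype: str) -> float:
    """Genotype p-value for binary awake outcomes, GEE with Fisher fallback.

    The GEE cannot converge when an hour is degenerate (e.g., every animal of
    a genotype awake in every bin); those hours fall back to a two-sided
    Fisher exact test on the pooled 2×2 table.
    """
    tab = sub.groupby("genotype")["awake"].agg(["sum", "size"])
    if (tab["sum"] == 0).all() or (tab["sum"] == tab["size"]).all():
        return 1.0
    degenerate = ((tab["sum"] == 0) | (tab["sum"] == tab["size"])).any()
    if not degenerate:
        try:
            return fit_phase_effect(
                sub, family="binomial", response_col="awake",
                reference_genotype=reference_genotype,
            ).p_value
        except (ValueError, np.linalg.LinAlgError):
            pass
    counts = tab.to_numpy()
    contingency = np.column_stack([counts[:, 0], counts[:, 1] - counts[:, 0]])
    return float(stats.fisher_exact(contingency)[1])


def adjust_fdr_by(p_values) -> np.ndarray:
    """Benjamini–Hochberg–Yekutieli step-up FDR adjustment (valid under
    arbitrary dependence): adjusted_i = min over j>=i of p_(j) * m * c(m) / j,
    capped at 1, where c(m) is the m-th harmonic number."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
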