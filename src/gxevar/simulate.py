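"""Synthetic thermal regimes and family-structured larval phenotypes.

Emulates a common-garden breeding design for early-life lake sturgeon:
five dams each crossed to two sires give ten half-sib (HS) families, every
family split across four egg-incubation treatments (constant cold 10 deg C,
constant warm ~18 deg C, a naturally fluctuating ambient regime, and a
strongly fluctuating "anthropogenic" regime).  Thirty larvae per family per
treatment are measured at hatch (N = 1,200).  A subset of five full-sib (FS)
families x 18 larvae x 4 treatments (N = 360) is followed in individual
rearing chambers across three raceways until emergence from the substrate.

Hatch traits follow the hierarchical model

    y_ijk = mu + treatment_i + a_j + b_ij + e_ijk,

with shared family effect a_j ~ N(0, sigma2_F), treatment-specific family
effect b_ij ~ N(0, sigma2_FS[i]) drawn independently across treatments (zero
cross-treatment covariance: a family that does well in one regime carries no
information about its rank in another), and heteroscedastic residuals
e_ijk ~ N(0, sigma2_eps[i]).  Emergence traits add raceway effects and
(optionally) Mean-T / degree-day covariate slopes, with the covariates
computed from a facility temperature series via :mod:`gxevar.thermal`.

Default variance parameters are the package's reference values for larval
lake sturgeon (per-treatment family and residual variances for body length,
body area, and yolk-sac area; FS family and homogeneous residual variances
for emergence time and growth).  Trait means and treatment shifts follow the
temperature-size rule (warm-incubated larvae hatch smaller) and staggered
hatch timing (warm hatches first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .thermal import (
    DegreeDayParams,
    ResidenceInterval,
    TemperatureSeries,
    degree_days,
    mean_temperature,
)

__all__ = [
    "TREATMENTS",
    "RegimeConfig",
    "TraitParams",
    "SimConfig",
    "generate_temperature_regime",
    "simulate_hatch_phenotypes",
    "simulate_emergence_outcomes",
    "default_facility_series",
]

#: Incubation treatment labels, coldest first (cold is the model reference level).
TREATMENTS = ("cold", "amb", "var", "warm")

REGIME_KINDS = ("constant", "natural_fluctuating", "anthropogenic_fluctuating")


@dataclass(frozen=True)
class RegimeConfig:
    """One thermal regime for the egg-incubation period.

    ``daily_change_range`` bounds the total within-day temperature excursion
    (max minus min) in deg C per day; the constant regimes pin it to (0, 0).
    Reference regimes: cold 10 deg C constant, warm 18 deg C constant, ambient
    ~1-3 deg/day, anthropogenic 1-9 deg/day.
    """

    regime_kind: str
    base_temp: float
    daily_change_range: tuple[float, float] = (0.0, 0.0)
    duration_days: int = 14
    readings_per_day: int = 24
    start: str = "2012-05-03"

    def __post_init__(self) -> None:
        if self.regime_kind not in REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.regime_kind!r}")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.readings_per_day < 1:
            raise ValueError("need at least one reading per day")
        lo, hi = self.daily_change_range
        if lo > hi or lo < 0:
            raise ValueError("daily_change_range must satisfy 0 <= min <= max")
        if self.regime_kind == "constant" and (lo, hi) != (0.0, 0.0):
            raise ValueError("constant regimes require daily_change_range (0, 0)")


STANDARD_REGIMES = {
    "cold": RegimeConfig("constant", 10.0),
    "warm": RegimeConfig("constant", 18.0),
    "amb": RegimeConfig("natural_fluctuating", 12.0, (1.0, 3.0)),
    "var": RegimeConfig("anthropogenic_fluctuating", 14.0, (1.0, 9.0)),
}


def generate_temperature_regime(config: RegimeConfig, seed: int) -> TemperatureSeries:
    """Simulate a logger series for one incubation regime.

    Constant regimes return ``base_temp`` everywhere.  Fluctuating regimes
    draw each day's total excursion uniformly within ``daily_change_range``
    and oscillate sinusoidally about ``base_temp``, rescaled so that the
    *sampled* daily range equals the drawn excursion exactly.
    """
    rng = np.random.default_rng(seed)
    n = config.duration_days * config.readings_per_day
    step = pd.Timedelta(24 / config.readings_per_day, "h")
    timestamps = pd.Timestamp(config.start) + step * np.arange(n)
    if config.regime_kind == "constant":
        temps = np.full(n, config.base_temp)
    else:
        lo, hi = config.daily_change_range
        temps = np.empty(n)
        m = config.readings_per_day
        phase = np.sin(2 * np.pi * np.arange(m) / m)
        for d in range(config.duration_days):
            amplitude = rng.uniform(lo, hi)
            if m == 1 or np.ptp(phase) == 0:
                wave = np.zeros(m)
            else:
                centred = phase - (phase.max() + phase.min()) / 2
                wave = amplitude * centred / np.ptp(phase)
            temps[d * m : (d + 1) * m] = config.base_temp + wave
    return TemperatureSeries(timestamps, temps)


@dataclass(frozen=True)
class TraitParams:
    """Generative parameters for a single trait.

    ``family_variances`` are the per-treatment family(-by-treatment)
    variances sigma2_FS; ``residual_variances`` the per-treatment residual
    variances sigma2_eps (a single shared value may be given under the key
    ``"all"``).  ``shared_family_variance`` is the across-treatment family
    main-effect variance sigma2_F (0 by default: the treatment-specific
    component carries the family signal).
    """

    mean: float
    treatment_effects: dict[str, float]
    family_variances: dict[str, float]
    residual_variances: dict[str, float]
    shared_family_variance: float = 0.0

    def __post_init__(self) -> None:
        for kind, variances in (
            ("family", self.family_variances),
            ("residual", self.residual_variances),
            ("shared family", {"": self.shared_family_variance}),
        ):
            for name, var in variances.items():
                if var < 0:
                    raise ValueError(f"negative variance for {kind} {name!r}")

    def residual_for(self, treatment: str) -> float:
        if "all" in self.residual_variances:
            return self.residual_variances["all"]
        return self.residual_variances[treatment]


def _hatch_defaults() -> dict[str, TraitParams]:
    return {
        "body_length_mm": TraitParams(
            mean=12.5,
            treatment_effects={"cold": 0.0, "amb": -0.2, "var": -0.4, "warm": -1.0},
            family_variances={"warm": 1.10, "var": 0.46, "amb": 0.44, "cold": 0.18},
            residual_variances={"warm": 0.74, "var": 0.66, "amb": 0.49, "cold": 0.35},
        ),
        "body_area_mm2": TraitParams(
            mean=23.0,
            treatment_effects={"cold": 0.0, "amb": -0.5, "var": -1.0, "warm": -2.0},
            family_variances={"warm": 9.27, "var": 10.53, "amb": 4.73, "cold": 1.21},
            residual_variances={"warm": 6.00, "var": 9.01, "amb": 8.45, "cold": 2.64},
        ),
        "yolk_sac_area_mm2": TraitParams(
            mean=7.5,
            treatment_effects={"cold": 0.0, "amb": -0.1, "var": -0.2, "warm": -0.4},
            family_variances={"warm": 0.10, "var": 0.32, "amb": 0.05, "cold": 0.03},
            residual_variances={"warm": 0.45, "var": 0.52, "amb": 0.75, "cold": 0.40},
        ),
    }


def _emergence_defaults() -> dict[str, TraitParams]:
    return {
        "days_to_emergence": TraitParams(
            mean=13.0,
            treatment_effects={"cold": 0.5, "amb": 0.0, "var": 0.0, "warm": 3.0},
            family_variances={t: 0.0 for t in TREATMENTS},
            residual_variances={"all": 2.69},
            shared_family_variance=0.36,
        ),
        "growth_mm": TraitParams(
            mean=12.5,
            treatment_effects={"cold": 1.0, "amb": 0.0, "var": 0.0, "warm": 1.0},
            family_variances={t: 0.0 for t in TREATMENTS},
            residual_variances={"all": 2.47},
            shared_family_variance=0.59,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Design and generative parameters for the synthetic study.

    The default sizes reproduce the reference design: 10 HS families x 4
    treatments x 30 larvae at hatch, and a 5-FS-family x 18-larvae subset per
    treatment followed to emergence across 3 raceways with 87% emergence
    success.
    """

    n_hs_families: int = 10
    n_fs_families: int = 5
    offspring_per_family_treatment_hatch: int = 30
    offspring_per_family_treatment_emergence: int = 18
    treatments: tuple[str, ...] = TREATMENTS
    n_raceways: int = 3
    emergence_probability: float = 0.87
    hatch_traits: dict[str, TraitParams] = field(default_factory=_hatch_defaults)
    emergence_traits: dict[str, TraitParams] = field(
        default_factory=_emergence_defaults
    )
    #: per-unit shifts of days_to_emergence with (centred) Mean T and Degree Days
    covariate_slopes: dict[str, float] = field(
        default_factory=lambda: {"mean_t": 0.0, "degree_days": 0.0}
    )
    #: raceway additive effects on days_to_emergence (chambers randomised, so ~0)
    raceway_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    fertilization_date: str = "2012-05-03"
    #: days post-fertilization to hatch, per treatment (warm hatches first)
    hatch_offsets_days: dict[str, float] = field(
        default_factory=lambda: {"warm": 6.0, "var": 9.0, "amb": 10.0, "cold": 12.0}
    )

    def __post_init__(self) -> None:
        if self.n_hs_families < 1 or self.n_hs_families % 2:
            raise ValueError("n_hs_families must be a positive even count")
        if not 1 <= self.n_fs_families <= self.n_hs_families // 2:
            raise ValueError("n_fs_families must be at most one per dam")
        if not 0.0 <= self.emergence_probability <= 1.0:
            raise ValueError("emergence_probability must lie in [0, 1]")
        for count in (
            self.offspring_per_family_treatment_hatch,
            self.offspring_per_family_treatment_emergence,
            self.n_raceways,
        ):
            if count < 1:
                raise ValueError("counts must be >= 1")
        if self.offspring_per_family_treatment_emergence > (
            self.offspring_per_family_treatment_hatch
        ):
            raise ValueError("emergence subset cannot exceed hatch offspring count")

    def with_trait(self, trait: str, params: TraitParams) -> "SimConfig":
        traits = dict(self.hatch_traits)
        traits[trait] = params
        return replace(self, hatch_traits=traits)


#: phenotype CSV column contract, shared with :mod:`gxevar.io`
PHENOTYPE_COLUMNS = [
    "individual_id",
    "dam_id",
    "sire_id",
    "hs_family",
    "fs_family",
    "treatment",
    "raceway",
    "body_length_mm",
    "body_area_mm2",
    "yolk_sac_area_mm2",
    "chamber_entry",
    "chamber_exit",
    "emerged",
    "emergence_length_mm",
    "growth_mm",
    "days_to_emergence",
    "mean_t_c",
    "degree_days_c",
]


def _family_structure(n_families: int) -> pd.DataFrame:
    """Ten-family reference scheme: dam d mated to sires 2d-1 and 2d."""
    dams = [f"D{(j // 2) + 1}" for j in range(n_families)]
    sires = [f"S{j + 1:02d}" for j in range(n_families)]
    labels = [f"F{j + 1:02d}" for j in range(n_families)]
    return pd.DataFrame({"hs_family": labels, "dam_id": dams, "sire_id": sires})


def simulate_hatch_phenotypes(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw the hatch phenotype table (one row per larva).

    Every trait is generated independently from its :class:`TraitParams`
    under the hierarchical model described in the module docstring.  The true
    family deviates are attached in ``table.attrs["true_effects"]`` keyed by
    ``(trait, family, treatment)`` (and ``(trait, family)`` for shared
    effects) so recovery tests can score the fit against the truth.
    """
    rng = np.random.default_rng(seed)
    families = _family_structure(config.n_hs_families)
    n_off = config.offspring_per_family_treatment_hatch
    rows = []
    fert = pd.Timestamp(config.fertilization_date)
    for treatment in config.treatments:
        entry = fert + pd.Timedelta(config.hatch_offsets_days[treatment], "D")
        for _, fam in families.iterrows():
            for k in range(n_off):
                rows.append(
                    {
                        "dam_id": fam["dam_id"],
                        "sire_id": fam["sire_id"],
                        "hs_family": fam["hs_family"],
                        "fs_family": fam["hs_family"],
                        "treatment": treatment,
                        "chamber_entry": entry,
                    }
                )
    table = pd.DataFrame(rows)
    table.insert(0, "individual_id", [f"L{i + 1:04d}" for i in range(len(table))])

    true_effects: dict[tuple, float] = {}
    for trait, params in config.hatch_traits.items():
        shared = {
            fam: rng.normal(0.0, np.sqrt(params.shared_family_variance))
            for fam in families["hs_family"]
        }
        by_treatment = {
            (fam, t): rng.normal(0.0, np.sqrt(params.family_variances[t]))
            for t in config.treatments
            for fam in families["hs_family"]
        }
        fam_t = zip(table["hs_family"].to_numpy(), table["treatment"].to_numpy())
        values = (
            params.mean
            + table["treatment"].map(params.treatment_effects).to_numpy(float)
            + table["hs_family"].map(shared).to_numpy(float)
            + np.array([by_treatment[key] for key in fam_t])
        )
        resid_sd = np.sqrt(
            table["treatment"].map(params.residual_for).to_numpy(float)
        )
        table[trait] = values + resid_sd * rng.standard_normal(len(table))
        for fam, dev in shared.items():
            true_effects[(trait, fam)] = dev
        for key, dev in by_treatment.items():
            true_effects[(trait, *key)] = dev

    for col in ("raceway", "chamber_exit", "emerged", "emergence_length_mm",
                "growth_mm", "days_to_emergence", "mean_t_c", "degree_days_c"):
        table[col] = pd.NA
    table = table[[c for c in PHENOTYPE_COLUMNS if c in table.columns]]
    table.attrs["true_effects"] = true_effects
    return table


def default_facility_series(config: SimConfig, seed: int) -> TemperatureSeries:
    """Ambient river-water series for the raceway facility, spanning the
    yolk-sac utilization period with margin."""
    regime = RegimeConfig(
        "natural_fluctuating",
        base_temp=12.0,
        daily_change_range=(1.0, 3.0),
        duration_days=45,
        readings_per_day=24,
        start=config.fertilization_date,
    )
    return generate_temperature_regime(regime, seed)


def simulate_emergence_outcomes(
    hatch: pd.DataFrame,
    config: SimConfig,
    facility_series: TemperatureSeries,
    seed: int,
) -> pd.DataFrame:
    """Subsample the full-sib subset and draw emergence outcomes.

    One full-sib family per dam (the dam's first-listed sire) enters the
    raceways; per family x treatment, ``offspring_per_family_treatment_emergence``
    larvae are subsampled from the hatch table and randomly assigned to
    raceways.  ``days_to_emergence`` and ``growth_mm`` are drawn from their
    trait models (family + raceway + residual deviates, plus centred Mean-T /
    Degree-Days slopes); each larva emerges with probability
    ``emergence_probability``; non-emerged rows carry no emergence fields.
    """
    rng = np.random.default_rng(seed)
    fs_labels = sorted(hatch["hs_family"].unique())[::2][: config.n_fs_families]
    n_sub = config.offspring_per_family_treatment_emergence
    day_params = config.emergence_traits["days_to_emergence"]
    growth_params = config.emergence_traits["growth_mm"]
    fam_day = {f: rng.normal(0, np.sqrt(day_params.shared_family_variance))
               for f in fs_labels}
    fam_growth = {f: rng.normal(0, np.sqrt(growth_params.shared_family_variance))
                  for f in fs_labels}
    fam_day_t = {
        (f, t): rng.normal(0, np.sqrt(day_params.family_variances[t]))
        for t in config.treatments for f in fs_labels
    }
    fam_growth_t = {
        (f, t): rng.normal(0, np.sqrt(growth_params.family_variances[t]))
        for t in config.treatments for f in fs_labels
    }

    picks = []
    for treatment in config.treatments:
        for fam in fs_labels:
            pool = hatch.index[
                (hatch["hs_family"] == fam) & (hatch["treatment"] == treatment)
            ].to_numpy()
            if len(pool) < n_sub:
                raise ValueError(
                    f"family {fam} has only {len(pool)} hatch rows in {treatment}"
                )
            picks.extend(rng.choice(pool, size=n_sub, replace=False))
    table = hatch.loc[picks].copy().reset_index(drop=True)
    table["fs_family"] = table["hs_family"]
    table["raceway"] = rng.integers(1, config.n_raceways + 1, size=len(table))

    mean_t = np.full(len(table), np.nan)
    dds = np.full(len(table), np.nan)
    days = np.full(len(table), np.nan)
    growth = np.full(len(table), np.nan)
    exits: list = [pd.NaT] * len(table)
    emerged = rng.random(len(table)) < config.emergence_probability
    slopes = config.covariate_slopes
    for i, row in enumerate(table.itertuples()):
        t = row.treatment
        base_days = (
            day_params.mean
            + day_params.treatment_effects[t]
            + fam_day[row.hs_family]
            + fam_day_t[(row.hs_family, t)]
            + config.raceway_effects[row.raceway - 1]
            + rng.normal(0, np.sqrt(day_params.residual_for(t)))
        )
        base_days = max(base_days, 1.0)
        entry = pd.Timestamp(row.chamber_entry)
        interval = ResidenceInterval(entry, entry + pd.Timedelta(base_days, "D"))
        if not facility_series.covers(interval):
            raise ValueError(
                f"residence interval {interval} outside facility series span"
            )
        mt = mean_temperature(facility_series, interval)
        dd = degree_days(facility_series, interval, DegreeDayParams(0.0))
        d = base_days + slopes.get("mean_t", 0.0) * (mt - 12.0)
        d += slopes.get("degree_days", 0.0) * (dd - 12.0 * base_days)
        d = max(d, 1.0)
        if emerged[i]:
            days[i] = d
            mean_t[i] = mt
            dds[i] = dd
            exits[i] = entry + pd.Timedelta(d, "D")
            growth[i] = (
                growth_params.mean
                + growth_params.treatment_effects[t]
                + fam_growth[row.hs_family]
                + fam_growth_t[(row.hs_family, t)]
                + rng.normal(0, np.sqrt(growth_params.residual_for(t)))
            )
    table["emerged"] = emerged
    table["days_to_emergence"] = days
    table["growth_mm"] = growth
    table["emergence_length_mm"] = table["body_length_mm"] + growth
    table["chamber_exit"] = exits
    table["mean_t_c"] = mean_t
    table["degree_days_c"] = dds
    table.attrs["true_effects"] = {
        **{("days_to_emergence", f): v for f, v in fam_day.items()},
        **{("growth_mm", f): v for f, v in fam_growth.items()},
        **{("days_to_emergence", *k): v for k, v in fam_day_t.items()},
        **{("growth_mm", *k): v for k, v in fam_growth_t.items()},
    }
    return table
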