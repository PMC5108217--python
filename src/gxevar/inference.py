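"""Derived inference: DIC model selection, posterior variance-ratio tests,
broad-sense heritability, and conditioned family-mean reaction norms.

* **DIC** = Dbar + pD with pD = Dbar - D(theta_bar): mean posterior deviance
  penalised by the effective parameter count; models within two DIC units
  are treated as equivalent and the simplest is preferred.
* **Variance-ratio test**: the posterior draws of two variance components are
  divided iteration-wise into an F-ratio profile; the one-tailed empirical
  tail-area probability is 1 - (#ratios > 1)/(#ratios).  Ties count as not
  exceeding (strict inequality), and the caller fixes which component is the
  numerator — the implementation warns, never swaps, when the observed
  median ratio contradicts the one-tailed expectation.
* **Broad-sense heritability** H^2 = 2 sigma2_F / (sigma2_F + sigma2_eps +
  ...), evaluated draw-by-draw and summarised as posterior mode with 95% HPD.
  The factor 2 converts full-sib family variance (~1/2 the genetic variance)
  to a total-genetic scale, making H^2 an upper bound on narrow-sense h^2.
* **Reaction norms**: per family x treatment, the posterior of the
  conditioned mean (fixed linear predictor + family-level effects), with
  family-level 95% intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import (
    DesignMatrices,
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    build_design,
    deviance,
    gibbs_sample,
)
from .posterior import hpd_interval, posterior_mode

__all__ = [
    "DicResult",
    "dic",
    "SelectionTable",
    "stepwise_select",
    "VarianceComparison",
    "variance_ratio_test",
    "tail_area_from_count",
    "HeritabilityEstimate",
    "heritability_draws",
    "conditional_family_means",
    "RegressionResult",
    "yolk_growth_regression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DicResult:
    dbar: float
    dhat: float

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def dic(draws: PosteriorDraws, design: DesignMatrices) -> DicResult:
    """Deviance information criterion from retained draws.

    ``Dbar`` averages the deviance over draws; ``Dhat`` evaluates it at the
    posterior mean of the location effects and residual variances.
    """
    p = design.n_location
    n_resid = len(design.residual_labels)
    expected = (
        design.fixed_labels
        + design.random_labels
        + [f"var[{c.name}]" for c in design.components]
        + [f"var[{r}]" for r in design.residual_labels]
    )
    if draws.labels != expected:
        raise ValueError("draws do not match the design's parameter layout")
    theta = draws.draws[:, :p]
    resvar = draws.draws[:, p + len(design.components):]
    # vectorised deviance over draws
    E = design.y[:, None] - design.W @ theta.T  # (n, m)
    sig2 = resvar.T[design.residual_index, :]  # (n, m)
    devs = np.sum(np.log(2 * np.pi * sig2) + E * E / sig2, axis=0)
    dbar = float(devs.mean())
    dhat = deviance(design, theta.mean(axis=0), resvar.mean(axis=0))
    result = DicResult(dbar=dbar, dhat=dhat)
    if result.pd < 0:
        warnings.warn(f"negative effective parameter count pD={result.pd:.2f}")
    return result


@dataclass
class SelectionTable:
    """Fit record for an ordered candidate list plus the selection decision."""

    rows: list[dict] = field(default_factory=list)
    chosen: ModelSpec | None = None
    chosen_draws: PosteriorDraws | None = None
    chosen_design: DesignMatrices | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: v for k, v in row.items() if k not in ("draws", "design")}
                for row in self.rows
            ]
        )


def _fixed_ci_spans_zero(draws: PosteriorDraws, design: DesignMatrices) -> list[str]:
    spanning = []
    for label in design.fixed_labels:
        if label == "intercept":
            continue
        d = draws.get(label)
        lo, hi = np.percentile(d, [2.5, 97.5])
        if lo < 0 < hi:
            spanning.append(label)
    return spanning


def stepwise_select(
    candidates: list[ModelSpec],
    table: pd.DataFrame,
    priors: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
) -> SelectionTable:
    """Fit candidates (ordered most complex -> simplest) and pick a best model.

    Every candidate is fitted and its DIC recorded, along with the fixed
    effects whose 95% credible interval spans zero (flagged for pruning).
    Among candidates whose DIC lies within two units of the minimum, the
    simplest wins.  If the winner has no family-by-treatment interaction but
    heterogeneous residuals, a homogeneous-residual variant is additionally
    fitted and preferred when within two DIC units.
    """
    if not candidates:
        raise ValueError("no candidate models supplied")
    result = SelectionTable()
    for i, spec in enumerate(candidates):
        design = build_design(table, spec)
        run = McmcSettings(
            settings.total_iterations, settings.burn_in, settings.thin,
            seed=settings.seed + i,
        )
        draws = gibbs_sample(design, priors, run)
        d = dic(draws, design)
        result.rows.append(
            {
                "model": spec.label,
                "dic": d.dic,
                "pd": d.pd,
                "complexity": spec.complexity,
                "ci_spans_zero": ",".join(_fixed_ci_spans_zero(draws, design)),
                "decision": "",
                "spec": spec,
                "draws": draws,
                "design": design,
            }
        )
        logger.info("fitted %s: DIC=%.2f pD=%.2f", spec.label, d.dic, d.pd)

    dics = np.array([row["dic"] for row in result.rows])
    best = float(dics.min())
    eligible = [row for row in result.rows if row["dic"] <= best + 2.0]
    chosen_row = min(
        eligible, key=lambda row: (row["complexity"], -result.rows.index(row))
    )
    chosen_row["decision"] = "chosen (simplest within 2 DIC of minimum)"
    for row in result.rows:
        if row is not chosen_row and row["dic"] <= best + 2.0:
            row["decision"] = "within 2 DIC, more complex"

    chosen_spec: ModelSpec = chosen_row["spec"]
    if (
        "family_by_treatment" not in chosen_spec.random
        and chosen_spec.heterogeneous_residual
    ):
        hom = chosen_spec.homogeneous()
        design = build_design(table, hom)
        run = McmcSettings(
            settings.total_iterations, settings.burn_in, settings.thin,
            seed=settings.seed + len(candidates),
        )
        draws = gibbs_sample(design, priors, run)
        d = dic(draws, design)
        row = {
            "model": hom.label,
            "dic": d.dic,
            "pd": d.pd,
            "complexity": hom.complexity,
            "ci_spans_zero": ",".join(_fixed_ci_spans_zero(draws, design)),
            "decision": "",
            "spec": hom,
            "draws": draws,
            "design": design,
        }
        result.rows.append(row)
        if d.dic <= chosen_row["dic"] + 2.0:
            chosen_row["decision"] = "superseded by homogeneous-residual variant"
            row["decision"] = "chosen (homogeneous residual within 2 DIC)"
            chosen_row = row

    result.chosen = chosen_row["spec"]
    result.chosen_draws = chosen_row["draws"]
    result.chosen_design = chosen_row["design"]
    return result


def tail_area_from_count(n_exceeding_one: int, n_total: int) -> float:
    """One-tailed empirical tail-area probability, 1 - N/total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_exceeding_one <= n_total:
        raise ValueError("need 0 <= n_exceeding_one <= n_total")
    return 1.0 - n_exceeding_one / n_total


@dataclass(frozen=True)
class VarianceComparison:
    numerator: str
    denominator: str
    ratio_draws: np.ndarray
    n_total: int
    n_exceeding_one: int

    @property
    def tail_area(self) -> float:
        return tail_area_from_count(self.n_exceeding_one, self.n_total)


def variance_ratio_test(
    numerator_draws,
    denominator_draws,
    numerator_label: str = "variance 1",
    denominator_label: str = "variance 2",
) -> VarianceComparison:
    """Iteration-wise posterior F-ratio profile of two variance components."""
    num = np.asarray(numerator_draws, dtype=float)
    den = np.asarray(denominator_draws, dtype=float)
    if num.size == 0 or num.shape != den.shape:
        raise ValueError("draw vectors must be non-empty and paired per iteration")
    ratios = num / den
    n_exceed = int(np.sum(ratios > 1.0))
    if np.median(ratios) < 1.0:
        warnings.warn(
            f"median F-ratio < 1: expected {numerator_label!r} to exceed "
            f"{denominator_label!r}"
        )
    return VarianceComparison(
        numerator=numerator_label,
        denominator=denominator_label,
        ratio_draws=ratios,
        n_total=num.size,
        n_exceeding_one=n_exceed,
    )


@dataclass(frozen=True)
class HeritabilityEstimate:
    draws: np.ndarray
    mode: float
    hpd_low: float
    hpd_high: float


def heritability_draws(
    family_var_draws,
    residual_var_draws,
    other_var_draws: tuple = (),
) -> HeritabilityEstimate:
    """Per-draw H^2 = 2 sigma2_F / (total phenotypic variance), summarised.

    The total is the sum of every variance component in the fitted model
    (family + residual + any others passed in), evaluated draw-by-draw.
    """
    fam = np.asarray(family_var_draws, dtype=float)
    res = np.asarray(residual_var_draws, dtype=float)
    parts = [fam, res] + [np.asarray(o, dtype=float) for o in other_var_draws]
    for p in parts:
        if p.shape != fam.shape:
            raise ValueError("all draw vectors must be paired per iteration")
        if np.any(p < 0):
            raise ValueError("variance draws must be non-negative")
    total = np.sum(parts, axis=0)
    h2 = np.where(total > 0, 2.0 * fam / total, 0.0)
    if h2.size >= 10 and np.ptp(h2) > 0:
        mode = posterior_mode(h2)
    else:
        mode = float(h2[0])
    lo, hi = hpd_interval(h2) if h2.size >= 2 else (float(h2[0]), float(h2[0]))
    return HeritabilityEstimate(draws=h2, mode=mode, hpd_low=lo, hpd_high=hi)


def conditional_family_means(
    draws: PosteriorDraws, design: DesignMatrices, prob: float = 0.95
) -> pd.DataFrame:
    """Reaction-norm table: conditioned family means per treatment.

    For each family x treatment cell, sums the posterior draws of the fixed
    linear predictor (intercept + treatment contrast, continuous covariates
    held at their centres) and the family-level random effects, and reports
    the posterior mean with central ``prob`` family-level interval bounds.
    """
    if not design.components:
        raise ValueError("fit includes no family-level random effects")
    spec = design.spec
    fam_col = spec.family_column
    families = sorted(design.frame[fam_col].unique())
    treatments = [
        lbl[len("treatment["):-1]
        for lbl in design.fixed_labels
        if lbl.startswith("treatment[")
    ]
    ref = [
        t for t in design.frame["treatment"].unique() if t not in treatments
    ] if "treatment" in design.frame.columns and treatments else []
    all_treatments = (ref + treatments) if treatments else [None]
    lo_q, hi_q = 50 * (1 - prob), 50 * (1 + prob)

    rows = []
    intercept = draws.get("intercept")
    for treatment in all_treatments:
        t_effect = (
            draws.get(f"treatment[{treatment}]")
            if treatment is not None and treatment not in ref
            else 0.0
        )
        for fam in families:
            total = intercept + t_effect
            found = False
            for comp in design.components:
                if comp.name == "family" and fam in comp.levels:
                    total = total + draws.get(f"family:{fam}")
                    found = True
                elif (
                    treatment is not None
                    and comp.name == f"family_by_treatment[{treatment}]"
                    and fam in comp.levels
                ):
                    total = total + draws.get(f"{comp.name}:{fam}")
                    found = True
            if not found:
                raise ValueError(
                    f"family {fam!r} absent from the fitted random effects"
                    + (f" in treatment {treatment!r}" if treatment else "")
                )
            lo, hi = np.percentile(total, [lo_q, hi_q])
            rows.append(
                {
                    "family": fam,
                    "treatment": treatment,
                    "mean": float(np.mean(total)),
                    "lower": float(lo),
                    "upper": float(hi),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def yolk_growth_regression(table: pd.DataFrame) -> RegressionResult:
    """OLS of growth (mm) on yolk-sac area (mm^2) over emerged larvae.

    Screens for a maternal-provisioning effect: a large R^2 would indicate
    that yolk reserves, not family identity, drive growth differences.
    """
    df = table.copy()
    for col in ("growth_mm", "yolk_sac_area_mm2"):
        if col not in df.columns:
            raise ValueError(f"table missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "emerged" in df.columns:
        df = df[df["emerged"].astype("boolean").fillna(False)]
    df = df.dropna(subset=["growth_mm", "yolk_sac_area_mm2"])
    if len(df) < 3:
        raise ValueError("need at least 3 emerged rows with both fields")
    x = df["yolk_sac_area_mm2"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("yolk-sac area is constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(df["growth_mm"].to_numpy(float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(df),
    )
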