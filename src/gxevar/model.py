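"""Bayesian linear mixed models with treatment-specific variance components.

The model family covers both study stages:

* hatch traits:  y = mu + Treatment + Family + Family x Treatment + e
* emergence traits:  y = mu + Treatment + MeanT + DegreeDays + Raceway
  + Family (+ Family x Treatment) + e

Family terms are random; the Family x Treatment interaction receives one
variance per treatment with zero covariance across treatments (an "idh"
structure: a family's effects in different environments are independent).
Residuals are heteroscedastic by treatment or homogeneous.

Fitting is by a blocked Gibbs sampler with conjugate updates:

1. all location effects (fixed + random) jointly from their multivariate
   Gaussian full conditional — a single sparse-free Cholesky solve per
   iteration, which mixes far better than scalar updates in crossed designs;
2. each random-effect variance from its inverse-gamma full conditional
   IG(a0 + q_g/2, b0 + ||u_g||^2 / 2);
3. each residual-group variance from IG(a0 + n_t/2, b0 + SS_t/2).

Variance priors default to the near-flat IG(shape=0.001, scale=0.001);
fixed effects get a Gaussian prior with variance 1e8 (effectively flat but
keeps every full conditional proper).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .simulate import TREATMENTS

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "McmcSettings",
    "DesignMatrices",
    "PosteriorDraws",
    "build_design",
    "gibbs_sample",
    "retained_draw_count",
    "deviance",
]

logger = logging.getLogger(__name__)

FIXED_TERMS = ("intercept", "treatment", "mean_t", "degree_days", "raceway")
RANDOM_TERMS = ("family", "family_by_treatment")

_COVARIATE_COLUMNS = {"mean_t": "mean_t_c", "degree_days": "degree_days_c"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate mixed model."""

    response: str
    fixed: tuple[str, ...] = ("intercept", "treatment")
    random: tuple[str, ...] = ("family_by_treatment",)
    heterogeneous_residual: bool = True
    family_column: str = "hs_family"

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        unknown = set(self.random) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if "intercept" not in self.fixed:
            raise ValueError("model must include an intercept")
        if "family_by_treatment" in self.random and "treatment" not in self.fixed:
            raise ValueError("family_by_treatment requires the treatment factor")

    @property
    def label(self) -> str:
        parts = list(self.fixed) + [f"({r})" for r in self.random]
        resid = "het" if self.heterogeneous_residual else "hom"
        return f"{self.response} ~ {' + '.join(parts)} [{resid} resid]"

    @property
    def complexity(self) -> int:
        """Term count used by the prefer-simpler selection rule."""
        return (
            len(self.fixed)
            + 2 * len(self.random)
            + (1 if self.heterogeneous_residual else 0)
        )

    def without_fixed(self, term: str) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))

    def without_random(self, term: str) -> "ModelSpec":
        return replace(self, random=tuple(t for t in self.random if t != term))

    def homogeneous(self) -> "ModelSpec":
        return replace(self, heterogeneous_residual=False)


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-gamma variance priors and the fixed-effect Gaussian prior."""

    shape: float = 0.001
    scale: float = 0.001
    fixed_effect_variance: float = 1e8

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("inverse-gamma shape and scale must be positive")
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed-effect prior variance must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run length: reference analyses used 400,000 iterations with a
    10,000 burn-in and thinning interval 100 (3,900 retained draws)."""

    total_iterations: int = 400_000
    burn_in: int = 10_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.total_iterations:
            raise ValueError("require 0 <= burn_in < total_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def retained_draw_count(settings: McmcSettings) -> int:
    """Number of post-burn-in, thinned draws: floor((total - burn_in)/thin)."""
    return (settings.total_iterations - settings.burn_in) // settings.thin


@dataclass(frozen=True)
class RandomComponent:
    name: str
    sl: slice  # columns of Z
    levels: tuple[str, ...]


@dataclass
class DesignMatrices:
    """Dense design for one model on one table (artifact plumbing)."""

    y: np.ndarray
    X: np.ndarray
    fixed_labels: list[str]
    Z: np.ndarray
    random_labels: list[str]
    components: list[RandomComponent]
    residual_labels: list[str]
    residual_index: np.ndarray
    frame: pd.DataFrame
    spec: ModelSpec
    centers: dict[str, float] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_location(self) -> int:
        return self.X.shape[1] + self.Z.shape[1]

    @property
    def W(self) -> np.ndarray:
        return np.hstack([self.X, self.Z]) if self.Z.size else self.X


def _treatment_categories(values: pd.Series) -> list[str]:
    present = set(values.unique())
    ordered = [t for t in TREATMENTS if t in present]
    extras = sorted(present - set(TREATMENTS))
    return ordered + extras


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Encode a phenotype table for one :class:`ModelSpec`.

    Treatment and raceway enter as treatment contrasts against a documented
    reference level (coldest treatment / first raceway); continuous thermal
    covariates are mean-centred (centres recorded for prediction); rows with
    a missing response or missing used covariates are dropped with a logged
    count.  Heterogeneous residual groups are the treatment labels.
    """
    if spec.response not in table.columns:
        raise ValueError(f"response {spec.response!r} not in table")
    used_cols = [spec.response]
    if "treatment" in spec.fixed or spec.heterogeneous_residual or (
        "family_by_treatment" in spec.random
    ):
        used_cols.append("treatment")
    for term, col in _COVARIATE_COLUMNS.items():
        if term in spec.fixed:
            used_cols.append(col)
    if "raceway" in spec.fixed:
        used_cols.append("raceway")
    if spec.random:
        used_cols.append(spec.family_column)
    missing_cols = [c for c in used_cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table missing columns: {missing_cols}")

    df = table.copy()
    for col in used_cols:
        if col in (spec.response, *_COVARIATE_COLUMNS.values()):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = df[used_cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_design: dropped %d rows with missing values", dropped)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete rows to fit")
    if "treatment" in used_cols:
        unknown = sorted(set(df["treatment"].unique()) - set(TREATMENTS))
        if unknown:
            raise ValueError(f"unknown treatment label(s): {unknown}")

    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)
    X_parts: list[np.ndarray] = [np.ones((n, 1))]
    fixed_labels = ["intercept"]
    centers: dict[str, float] = {}

    if "treatment" in spec.fixed:
        cats = _treatment_categories(df["treatment"])
        for level in cats[1:]:
            X_parts.append((df["treatment"] == level).to_numpy(float)[:, None])
            fixed_labels.append(f"treatment[{level}]")
    for term, col in _COVARIATE_COLUMNS.items():
        if term in spec.fixed:
            vals = df[col].to_numpy(float)
            if np.ptp(vals) == 0:
                raise ValueError(f"covariate {col!r} is constant")
            centers[term] = float(vals.mean())
            X_parts.append((vals - centers[term])[:, None])
            fixed_labels.append(term)
    if "raceway" in spec.fixed:
        levels = sorted(df["raceway"].unique())
        for level in levels[1:]:
            X_parts.append((df["raceway"] == level).to_numpy(float)[:, None])
            fixed_labels.append(f"raceway[{level}]")
    X = np.hstack(X_parts)

    Z_parts: list[np.ndarray] = []
    random_labels: list[str] = []
    components: list[RandomComponent] = []
    col_offset = 0
    fam = df[spec.family_column] if spec.random else None
    if "family" in spec.random:
        levels = tuple(sorted(fam.unique()))
        block = np.column_stack([(fam == f).to_numpy(float) for f in levels])
        components.append(
            RandomComponent("family", slice(col_offset, col_offset + len(levels)), levels)
        )
        random_labels += [f"family:{f}" for f in levels]
        Z_parts.append(block)
        col_offset += len(levels)
    if "family_by_treatment" in spec.random:
        cats = _treatment_categories(df["treatment"])
        fam_levels = sorted(fam.unique())
        for t in cats:
            in_t = (df["treatment"] == t).to_numpy()
            levels = tuple(f for f in fam_levels if ((fam == f).to_numpy() & in_t).any())
            if not levels:
                continue
            block = np.column_stack(
                [((fam == f).to_numpy() & in_t).astype(float) for f in levels]
            )
            name = f"family_by_treatment[{t}]"
            components.append(
                RandomComponent(name, slice(col_offset, col_offset + len(levels)), levels)
            )
            random_labels += [f"{name}:{f}" for f in levels]
            Z_parts.append(block)
            col_offset += len(levels)
    Z = np.hstack(Z_parts) if Z_parts else np.empty((n, 0))

    if spec.heterogeneous_residual:
        cats = _treatment_categories(df["treatment"])
        residual_labels = [f"residual[{t}]" for t in cats]
        code = {t: i for i, t in enumerate(cats)}
        residual_index = df["treatment"].map(code).to_numpy(dtype=np.intp)
        counts = np.bincount(residual_index, minlength=len(cats))
        empty = [cats[i] for i in np.flatnonzero(counts == 0)]
        if empty:
            raise ValueError(f"residual group(s) with zero observations: {empty}")
    else:
        residual_labels = ["residual"]
        residual_index = np.zeros(n, dtype=np.intp)

    return DesignMatrices(
        y=y,
        X=X,
        fixed_labels=fixed_labels,
        Z=Z,
        random_labels=random_labels,
        components=components,
        residual_labels=residual_labels,
        residual_index=residual_index,
        frame=df,
        spec=spec,
        centers=centers,
    )


@dataclass
class PosteriorDraws:
    """Retained MCMC samples, one column per parameter.

    Column order: fixed effects, random-effect levels, one variance per
    random component (``var[...]``), one variance per residual group
    (``var[residual...]``).
    """

    labels: list[str]
    draws: np.ndarray
    settings: McmcSettings

    def __post_init__(self) -> None:
        if self.draws.shape[1] != len(self.labels):
            raise ValueError("draws and labels disagree on parameter count")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def get(self, label: str) -> np.ndarray:
        try:
            return self.draws[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no parameter {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, settings: McmcSettings | None = None) -> "PosteriorDraws":
        frame = pd.read_csv(path)
        settings = settings or McmcSettings(
            total_iterations=len(frame) + 1, burn_in=0, thin=1
        )
        return cls(list(frame.columns), frame.to_numpy(float), settings)

    def variance_labels(self) -> list[str]:
        return [l for l in self.labels if l.startswith("var[")]


def _sample_inverse_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """One draw from IG(shape, scale): 1 / Gamma(shape, rate=scale)."""
    g = rng.gamma(shape, 1.0 / scale)
    # guard against underflow at tiny shapes
    return 1.0 / max(g, np.finfo(float).tiny)


def gibbs_sample(
    design: DesignMatrices,
    priors: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    *,
    fix_residual_variances: np.ndarray | None = None,
    fix_component_variances: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; deterministic given ``settings.seed``.

    ``fix_residual_variances`` / ``fix_component_variances`` pin those
    variances instead of sampling them (used by conjugate-oracle checks).
    """
    rng = np.random.default_rng(settings.seed)
    y = design.y
    W = design.W
    n, p = W.shape
    p_fixed = design.X.shape[1]
    n_resid = len(design.residual_labels)
    n_comp = len(design.components)

    group_idx = [np.flatnonzero(design.residual_index == g) for g in range(n_resid)]
    for g, idx in enumerate(group_idx):
        if idx.size == 0:
            raise ValueError(
                f"residual group {design.residual_labels[g]!r} has no observations"
            )
    G = np.stack([W[idx].T @ W[idx] for idx in group_idx])  # (T, p, p)
    b = np.stack([W[idx].T @ y[idx] for idx in group_idx])  # (T, p)
    n_t = np.array([idx.size for idx in group_idx], dtype=float)

    comp_slices = [
        slice(p_fixed + c.sl.start, p_fixed + c.sl.stop) for c in design.components
    ]
    q_c = np.array([c.sl.stop - c.sl.start for c in design.components], dtype=float)

    y_var = float(np.var(y))
    sigma2_e = (
        np.asarray(fix_residual_variances, dtype=float).copy()
        if fix_residual_variances is not None
        else np.full(n_resid, y_var if y_var > 0 else 1.0)
    )
    sigma2_c = (
        np.asarray(fix_component_variances, dtype=float).copy()
        if fix_component_variances is not None
        else np.full(n_comp, max(y_var / 2, 1e-3))
    )
    if sigma2_e.shape != (n_resid,):
        raise ValueError("fix_residual_variances has wrong length")
    if sigma2_c.shape != (n_comp,):
        raise ValueError("fix_component_variances has wrong length")

    a0, b0 = priors.shape, priors.scale
    prior_prec = np.full(p, 1.0 / priors.fixed_effect_variance)

    n_keep = retained_draw_count(settings)
    out = np.empty((n_keep, p + n_comp + n_resid))
    keep = 0
    resid = np.empty(n)
    for it in range(1, settings.total_iterations + 1):
        lam = 1.0 / sigma2_e
        C = np.tensordot(lam, G, axes=1)
        rhs = lam @ b
        diag = prior_prec.copy()
        for c, sl in enumerate(comp_slices):
            diag[sl] = 1.0 / sigma2_c[c]
        C[np.diag_indices_from(C)] += diag
        L = cholesky(C, lower=True, check_finite=False)
        mean = cho_solve((L, True), rhs, check_finite=False)
        noise = solve_triangular(
            L.T, rng.standard_normal(p), lower=False, check_finite=False
        )
        theta = mean + noise

        if fix_component_variances is None:
            for c, sl in enumerate(comp_slices):
                u = theta[sl]
                sigma2_c[c] = _sample_inverse_gamma(
                    rng, a0 + q_c[c] / 2.0, b0 + float(u @ u) / 2.0
                )
        if fix_residual_variances is None:
            np.subtract(y, W @ theta, out=resid)
            for g, idx in enumerate(group_idx):
                ss = float(resid[idx] @ resid[idx])
                sigma2_e[g] = _sample_inverse_gamma(
                    rng, a0 + n_t[g] / 2.0, b0 + ss / 2.0
                )

        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if keep < n_keep:
                out[keep, :p] = theta
                out[keep, p : p + n_comp] = sigma2_c
                out[keep, p + n_comp :] = sigma2_e
                keep += 1

    labels = (
        design.fixed_labels
        + design.random_labels
        + [f"var[{c.name}]" for c in design.components]
        + [f"var[{r}]" for r in design.residual_labels]
    )
    return PosteriorDraws(labels=labels, draws=out[:keep], settings=settings)


def deviance(
    design: DesignMatrices,
    location: np.ndarray,
    residual_variances: np.ndarray,
) -> float:
    """-2 x Gaussian log-likelihood of the response at a parameter point."""
    location = np.asarray(location, dtype=float)
    residual_variances = np.asarray(residual_variances, dtype=float)
    if location.shape != (design.n_location,):
        raise ValueError("location vector has wrong length")
    if residual_variances.shape != (len(design.residual_labels),):
        raise ValueError("residual-variance vector has wrong length")
    if np.any(residual_variances <= 0):
        raise ValueError("residual variances must be positive")
    e = design.y - design.W @ location
    sig2 = residual_variances[design.residual_index]
    return float(np.sum(np.log(2 * math.pi * sig2) + e * e / sig2))
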