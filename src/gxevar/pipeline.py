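"""End-to-end analysis pipeline: simulate (or load) -> fit -> select ->
compare -> report.

For each analysed trait the pipeline fits the ordered candidate models,
applies DIC selection, and writes:

* ``selection_<trait>.csv`` — candidate DICs and the decision;
* ``summary_<trait>.csv`` — variance-component modes and 95% HPD bounds for
  the chosen model (layout: component, estimate, bounds);
* ``comparisons_<trait>.csv`` — pairwise one-tailed variance-ratio tests
  (variance1, variance2, N, tail_area) when the chosen model retains the
  family-by-treatment interaction;
* ``heritability_<trait>.csv`` — H^2 mode and HPD when the chosen model has
  a family effect but no interaction;
* ``reaction_norms_<trait>.csv`` — conditioned family means per treatment;
* ``run_log.txt`` — one structured line per MCMC run.

All randomness flows from the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, simulate
from .model import McmcSettings, ModelSpec
from .posterior import heidelberger_welch, summarize_draws

__all__ = ["hatch_candidates", "emergence_candidates", "run_pipeline"]


def hatch_candidates(trait: str) -> list[ModelSpec]:
    """Candidate models for a hatch trait, most complex first."""
    full = ModelSpec(
        response=trait,
        fixed=("intercept", "treatment"),
        random=("family", "family_by_treatment"),
        heterogeneous_residual=True,
        family_column="hs_family",
    )
    return [
        full,
        full.without_random("family"),
        full.without_random("family_by_treatment"),
    ]


def emergence_candidates(trait: str) -> list[ModelSpec]:
    """Candidate models for an emergence trait, most complex first."""
    full = ModelSpec(
        response=trait,
        fixed=("intercept", "treatment", "mean_t", "degree_days", "raceway"),
        random=("family", "family_by_treatment"),
        heterogeneous_residual=True,
        family_column="fs_family",
    )
    reduced = full.without_random("family_by_treatment")
    return [
        full,
        reduced,
        reduced.without_fixed("raceway"),
        reduced.without_fixed("raceway").without_fixed("mean_t"),
    ]


def _variance_summary(selection: inference.SelectionTable) -> pd.DataFrame:
    draws = selection.chosen_draws
    by_label = {l: draws.get(l) for l in draws.variance_labels()}
    summary = summarize_draws(by_label)
    summary = summary.rename(columns={"parameter": "component", "mode": "estimate"})
    return summary[["component", "estimate", "hpd_low", "hpd_high", "mean", "ess"]]


def _analyse_trait(
    trait: str,
    table: pd.DataFrame,
    candidates: list[ModelSpec],
    config: io.PipelineConfig,
    out: Path,
    log_lines: list[str],
) -> None:
    settings = replace(
        config.mcmc, seed=config.mcmc.seed + zlib.crc32(trait.encode()) % 1000
    )
    selection = inference.stepwise_select(candidates, table, config.priors, settings)
    prov = config.provenance()
    io.write_table(selection.to_frame(), out / f"selection_{trait}.csv", prov)
    io.write_table(_variance_summary(selection), out / f"summary_{trait}.csv", prov)

    draws = selection.chosen_draws
    design = selection.chosen_design
    for label in draws.variance_labels():
        diag = heidelberger_welch(draws.get(label))
        log_lines.append(
            f"trait={trait} model='{selection.chosen.label}' param={label} "
            f"stationary={diag.stationary} p={diag.pvalue:.3f} "
            f"retained={draws.n_retained}"
        )

    interaction_vars = [
        l for l in draws.variance_labels() if l.startswith("var[family_by_treatment")
    ]
    if interaction_vars:
        rows = []
        for num_label, den_label in config.comparisons:
            if num_label not in draws.labels or den_label not in draws.labels:
                continue
            comp = inference.variance_ratio_test(
                draws.get(num_label), draws.get(den_label), num_label, den_label
            )
            rows.append(
                {
                    "variance1": comp.numerator,
                    "variance2": comp.denominator,
                    "N": comp.n_exceeding_one,
                    "n_total": comp.n_total,
                    "tail_area": round(comp.tail_area, 3),
                }
            )
        if rows:
            io.write_table(
                pd.DataFrame(rows), out / f"comparisons_{trait}.csv", prov
            )
    else:
        # family retained without an interaction -> heritability is reportable
        fam_labels = [l for l in draws.variance_labels() if l == "var[family]"]
        if fam_labels:
            resid = [l for l in draws.variance_labels() if l.startswith("var[residual")]
            others = [
                draws.get(l)
                for l in draws.variance_labels()
                if l not in fam_labels + resid
            ]
            resid_draws = np.mean([draws.get(l) for l in resid], axis=0)
            h2 = inference.heritability_draws(
                draws.get("var[family]"), resid_draws, tuple(others)
            )
            io.write_table(
                pd.DataFrame(
                    [{"trait": trait, "h2_mode": h2.mode,
                      "hpd_low": h2.hpd_low, "hpd_high": h2.hpd_high}]
                ),
                out / f"heritability_{trait}.csv",
                prov,
            )

    if design.components:
        norms = inference.conditional_family_means(draws, design)
        io.write_table(norms, out / f"reaction_norms_{trait}.csv", prov)


def run_pipeline(config: io.PipelineConfig) -> Path:
    """Run the full analysis described by ``config``; returns the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config {config.digest()} seed {config.seed}"]
    prov = config.provenance()

    if config.temperature_csv:
        facility = io.read_temperature_csv(config.temperature_csv)
    else:
        facility = simulate.default_facility_series(config.simulation, config.seed)
        io.write_temperature_csv(facility, out / "facility_temperature.csv",
                                 [f"{k}: {v}" for k, v in prov.items()])
    if config.phenotype_csv:
        hatch = io.read_phenotype_csv(config.phenotype_csv)
        emergence = hatch[hatch["emerged"].notna()] if "emerged" in hatch else hatch
    else:
        hatch = simulate.simulate_hatch_phenotypes(config.simulation, config.seed)
        emergence = simulate.simulate_emergence_outcomes(
            hatch, config.simulation, facility, config.seed + 1
        )
        io.write_phenotype_csv(hatch, out / "hatch_phenotypes.csv",
                               [f"{k}: {v}" for k, v in prov.items()])
        io.write_phenotype_csv(emergence, out / "emergence_phenotypes.csv",
                               [f"{k}: {v}" for k, v in prov.items()])

    for trait in config.hatch_traits:
        _analyse_trait(trait, hatch, hatch_candidates(trait), config, out, log_lines)
    for trait in config.emergence_traits:
        _analyse_trait(
            trait, emergence, emergence_candidates(trait), config, out, log_lines
        )

    if {"growth_mm", "yolk_sac_area_mm2"} <= set(emergence.columns):
        try:
            reg = inference.yolk_growth_regression(emergence)
            io.write_table(
                pd.DataFrame([vars(reg)]), out / "yolk_growth_regression.csv", prov
            )
        except ValueError as exc:
            log_lines.append(f"yolk regression skipped: {exc}")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
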