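"""CSV formats and the structured pipeline configuration.

Single tabular dialect: RFC-4180 CSV, UTF-8, ISO-8601 timestamps.  Output
tables carry a provenance header of ``#``-prefixed comment lines (config
hash, seed, sampler settings) which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import McmcSettings, PriorSpec
from .simulate import PHENOTYPE_COLUMNS, TREATMENTS, SimConfig, TraitParams
from .thermal import TemperatureSeries

__all__ = [
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_temperature_csv",
    "write_temperature_csv",
    "PipelineConfig",
    "write_table",
]

MANDATORY_COLUMNS = [
    "individual_id",
    "hs_family",
    "fs_family",
    "treatment",
]

_TIMESTAMP_COLUMNS = ("chamber_entry", "chamber_exit")


def read_phenotype_csv(path, treatments: tuple[str, ...] = TREATMENTS) -> pd.DataFrame:
    """Read a phenotype table, validating the documented schema.

    Unknown treatment labels and missing mandatory columns are rejected with
    messages naming the offender.
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype CSV missing mandatory columns: {missing}")
    unknown = sorted(set(table["treatment"].dropna().unique()) - set(treatments))
    if unknown:
        raise ValueError(f"unknown treatment label(s): {unknown}")
    dupes = table["individual_id"][table["individual_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate individual_id(s): {sorted(dupes.unique())[:5]}")
    for col in _TIMESTAMP_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_datetime(table[col], errors="coerce")
    if "emerged" in table.columns:
        table["emerged"] = table["emerged"].map(
            {True: True, False: False, "True": True, "False": False}
        )
    return table


def write_phenotype_csv(table: pd.DataFrame, path, header_lines: list[str] = ()) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in PHENOTYPE_COLUMNS
    ]
    _write_with_header(table[cols], path, header_lines)


def read_temperature_csv(path) -> TemperatureSeries:
    frame = pd.read_csv(path, comment="#")
    missing = {"timestamp", "temperature_c"} - set(frame.columns)
    if missing:
        raise ValueError(f"temperature CSV missing columns: {sorted(missing)}")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return TemperatureSeries.from_frame(frame)


def write_temperature_csv(
    series: TemperatureSeries, path, header_lines: list[str] = ()
) -> None:
    _write_with_header(series.to_frame(), path, header_lines)


def _write_with_header(frame: pd.DataFrame, path, header_lines) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def write_table(frame: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write an output table with a provenance comment header."""
    lines = [f"{k}: {v}" for k, v in (provenance or {}).items()]
    _write_with_header(frame, path, lines)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; fully determines every output byte."""

    output_dir: str = "gxevar_out"
    seed: int = 1
    phenotype_csv: str | None = None  # None -> simulate
    temperature_csv: str | None = None
    simulation: SimConfig = field(default_factory=SimConfig)
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(4000, 500, 5, 0))
    priors: PriorSpec = field(default_factory=PriorSpec)
    hatch_traits: tuple[str, ...] = ("body_length_mm",)
    emergence_traits: tuple[str, ...] = ("days_to_emergence",)
    comparisons: tuple[tuple[str, str], ...] = (
        ("var[family_by_treatment[warm]]", "var[family_by_treatment[var]]"),
        ("var[family_by_treatment[warm]]", "var[family_by_treatment[amb]]"),
        ("var[family_by_treatment[warm]]", "var[family_by_treatment[cold]]"),
        ("var[family_by_treatment[var]]", "var[family_by_treatment[amb]]"),
        ("var[family_by_treatment[var]]", "var[family_by_treatment[cold]]"),
        ("var[family_by_treatment[amb]]", "var[family_by_treatment[cold]]"),
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("output_dir", "seed", "phenotype_csv", "temperature_csv"):
            if key in raw:
                kwargs[key] = raw[key]
        if "mcmc" in raw:
            kwargs["mcmc"] = McmcSettings(**raw["mcmc"])
        if "priors" in raw:
            kwargs["priors"] = PriorSpec(**raw["priors"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            for group in ("hatch_traits", "emergence_traits"):
                if group in sim:
                    sim[group] = {
                        name: TraitParams(**params)
                        for name, params in sim[group].items()
                    }
            kwargs["simulation"] = SimConfig(**sim)
        for key in ("hatch_traits", "emergence_traits"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(tuple(pair) for pair in raw["comparisons"])
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance headers."""

        def default(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        payload = asdict_safe(self)
        payload.pop("output_dir", None)  # where outputs land is not what they are
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "config_sha256": self.digest(),
            "seed": self.seed,
            "mcmc": (
                f"total={self.mcmc.total_iterations} burn_in={self.mcmc.burn_in} "
                f"thin={self.mcmc.thin}"
            ),
            "priors": f"IG(shape={self.priors.shape}, scale={self.priors.scale})",
        }


def asdict_safe(obj) -> dict:
    try:
        return asdict(obj)
    except TypeError:
        return vars(obj)
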