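"""CSV/YAML input-output and the capture-analysis report.

Formats
-------
Time-course CSV: one row per sample; a ``time`` column (hours), an
``od600`` column, and species columns with unit suffixes, e.g.
``xylose_gL``, ``lactate_mM``, ``lactate13C_gL``.

Rate-table CSV: species rows × strain columns, cells ``value ± sd`` in
mmol gDCW^-1 h^-1 (the layout of the published strain comparison table).
A ``label_fraction`` row is accepted for strains whose CO2 uptake is to be
inferred.

Config YAML: constants overrides, strain genotype flags, analysis window,
estimator choices and Monte-Carlo settings (schema in ``AnalysisConfig``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .balances import monte_carlo_propagate, round_half_away, strain_summary
from .constants import (
    CONSUMPTION,
    NetworkConstants,
    RateMeasurement,
    StrainConfig,
    StrainRateTable,
    validate_rate_table,
)
from .timecourse import TimeCourse

__all__ = [
    "AnalysisConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_rate_table_csv",
    "write_rate_table_csv",
    "reference_rate_tables",
    "run_capture_analysis",
]

_UNIT_SUFFIX = {"gL": "g/L", "mM": "mM"}
_SUFFIX_FOR = {v: k for k, v in _UNIT_SUFFIX.items()}
_PM_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(?:±|\+/-)\s*([0-9.eE+-]+)\s*$")

_SPECIES_ROWS = ("xylose", "glycerol", "co2_uptake", "lactate", "acetate", "ethanol")
_DIRECTION = {
    "xylose": CONSUMPTION,
    "glycerol": CONSUMPTION,
    "co2_uptake": CONSUMPTION,
    "lactate": "production",
    "acetate": "production",
    "ethanol": "production",
}


@dataclass
class AnalysisConfig:
    """Everything a full capture analysis needs besides the data files."""

    constants: NetworkConstants = field(default_factory=NetworkConstants)
    strains: dict[str, StrainConfig] = field(default_factory=dict)
    control_strain: Optional[str] = None
    window_span_h: float = 12.0
    rate_estimator: str = "endpoint"
    mc_draws: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        constants = NetworkConstants()
        overrides = raw.get("constants", {})
        if overrides:
            constants = constants.with_overrides(
                **{
                    k: ({**getattr(constants, k), **v} if isinstance(v, dict) else v)
                    for k, v in overrides.items()
                }
            )
        strains: dict[str, StrainConfig] = {}
        for sid, info in (raw.get("strains") or {}).items():
            if sid in strains:
                raise ValueError(f"strain {sid!r} defined twice")
            strains[sid] = StrainConfig(
                strain_id=sid,
                rubisco_active=bool(info.get("rubisco_active", True)),
                prk_active=bool(info.get("prk_active", True)),
                notes=str(info.get("notes", "")),
            )
        return cls(
            constants=constants,
            strains=strains,
            control_strain=raw.get("control_strain"),
            window_span_h=float(raw.get("window_span_h", 12.0)),
            rate_estimator=str(raw.get("rate_estimator", "endpoint")),
            mc_draws=int(raw.get("mc_draws", 10_000)),
            seed=int(raw.get("seed", 0)),
        )


def _split_column(name: str) -> tuple[str, str]:
    if "_" not in name:
        raise ValueError(f"column {name!r} lacks a unit suffix (e.g. lactate_mM)")
    species, suffix = name.rsplit("_", 1)
    if suffix not in _UNIT_SUFFIX:
        raise ValueError(f"unparseable unit suffix in column {name!r}")
    return species, _UNIT_SUFFIX[suffix]


def read_timecourse_csv(path: str | Path) -> TimeCourse:
    """Read a unit-suffixed time-course CSV; rows are sorted by time."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    if "od600" not in df.columns:
        raise ValueError(f"{path}: missing 'od600' column")
    df = df.sort_values("time")
    if df["time"].duplicated().any():
        raise ValueError(f"{path}: duplicate timestamps")
    concentrations: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for col in df.columns:
        if col in ("time", "od600"):
            continue
        species, unit = _split_column(col)
        concentrations[species] = df[col].to_numpy(dtype=float)
        units[species] = unit
    return TimeCourse(
        times=df["time"].to_numpy(dtype=float),
        od600=df["od600"].to_numpy(dtype=float),
        concentrations=concentrations,
        units=units,
    )


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    data = {"time": tc.times, "od600": tc.od600}
    for species, series in tc.concentrations.items():
        data[f"{species}_{_SUFFIX_FOR[tc.units[species]]}"] = series
    pd.DataFrame(data).to_csv(path, index=False)


def _parse_pm(cell) -> tuple[float, float]:
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        return float(cell), 0.0
    text = str(cell).strip()
    if text in ("", "-", "–", "nan"):
        return 0.0, 0.0
    m = _PM_RE.match(text)
    if m:
        return float(m.group(1)), float(m.group(2))
    try:
        return float(text), 0.0
    except ValueError as exc:
        raise ValueError(f"malformed rate cell {cell!r}") from exc


def read_rate_table_csv(
    path: str | Path,
    strain_configs: Optional[dict[str, StrainConfig]] = None,
    constants: Optional[NetworkConstants] = None,
) -> dict[str, StrainRateTable]:
    """Parse a species × strain rate table into per-strain tables."""
    constants = constants or NetworkConstants()
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty rate table")
    unknown = [r for r in df.index if r not in _SPECIES_ROWS + ("label_fraction",)]
    if unknown:
        raise ValueError(f"{path}: unknown species rows {unknown}")
    tables: dict[str, StrainRateTable] = {}
    for strain_id in df.columns:
        col = df[strain_id]

        def meas(species: str) -> RateMeasurement:
            value, sd = _parse_pm(col.get(species, 0.0))
            name = "co2" if species == "co2_uptake" else species
            return RateMeasurement(name, value, sd, _DIRECTION[species])

        cfg = (strain_configs or {}).get(strain_id, StrainConfig(strain_id))
        # a printed dash is an explicit "no uptake"; a truly empty cell
        # means the flux is still to be inferred from the label fraction
        co2 = None
        if "co2_uptake" in df.index:
            cell = col["co2_uptake"]
            empty = cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == ""
            if not empty:
                value, sd = _parse_pm(cell)
                co2 = RateMeasurement("co2", value, sd, CONSUMPTION)
        label = None
        if "label_fraction" in df.index:
            value, _ = _parse_pm(col["label_fraction"])
            label = value or None
        table = StrainRateTable(
            strain=cfg,
            xylose=meas("xylose"),
            glycerol=meas("glycerol"),
            lactate=meas("lactate"),
            acetate=meas("acetate"),
            ethanol=meas("ethanol"),
            co2_uptake=co2,
            label_fraction=label,
        )
        tables[strain_id] = validate_rate_table(table, constants)
    return tables


def write_rate_table_csv(
    tables: dict[str, StrainRateTable], path: str | Path
) -> None:
    rows = {}
    for species in _SPECIES_ROWS:
        row = {}
        for sid, t in tables.items():
            m = t.co2_uptake if species == "co2_uptake" else getattr(t, species)
            row[sid] = "" if m is None else f"{m.value} ± {m.sd}"
        rows[species] = row
    pd.DataFrame(rows).T.rename_axis("species").to_csv(path)


def reference_rate_tables() -> dict[str, StrainRateTable]:
    """The packaged reference strain-comparison table (three strains)."""
    path = Path(__file__).parent / "data" / "strain_rates.csv"
    configs = {
        "197-2021": StrainConfig("197-2021", rubisco_active=False, prk_active=False,
                                 notes="control: inactivated PRK and Rubisco"),
        "7002": StrainConfig("7002", notes="PRK + Synechococcus 7002 Rubisco"),
        "RPE": StrainConfig("RPE", notes="PRK + R. pachyptila endosymbiont Rubisco"),
    }
    return read_rate_table_csv(path, strain_configs=configs)


_REPORT_ROWS = (
    ("co2_uptake", 2),
    ("released_co2", 2),
    ("total_carbon_consumption", 2),
    ("total_carbon_production", 2),
    ("carbon_recovery", 2),
    ("nadh_ratio", 2),
    ("bypass_fraction", 3),
    ("label_fraction", 4),
)


def run_capture_analysis(
    tables: dict[str, StrainRateTable],
    config: Optional[AnalysisConfig] = None,
    propagate_uncertainty: bool = False,
) -> dict:
    """Full per-strain ledger analysis plus cross-strain comparisons.

    Returns a JSON-serialisable report: a provenance header, per-strain
    scalar results (optionally with Monte-Carlo SDs), and fold comparisons
    of the CO2-uptake flux between every pair of bypass-active strains.
    """
    config = config or AnalysisConfig()
    constants = config.constants
    report: dict = {
        "provenance": {
            "dcw_per_od": constants.dcw_per_od,
            "carbon_atoms": constants.carbon_atoms,
            "nadh_consumed_per": constants.nadh_consumed_per,
            "nadh_produced_per": constants.nadh_produced_per,
            "window_span_h": config.window_span_h,
            "rate_estimator": config.rate_estimator,
            "mc_draws": config.mc_draws if propagate_uncertainty else 0,
            "seed": config.seed,
        },
        "strains": {},
        "comparisons": {},
    }
    for sid, table in tables.items():
        try:
            summary = strain_summary(table, constants)
        except ValueError as exc:
            raise ValueError(f"strain {sid!r}: {exc}") from exc
        entry = {k: summary[k] for k, _ in _REPORT_ROWS}
        entry["redox_feasible"] = bool(summary["redox_feasible"])
        if propagate_uncertainty:
            mc = monte_carlo_propagate(
                table, constants, n_draws=config.mc_draws, seed=config.seed
            )
            entry["sd"] = {k: mc[k][1] for k, _ in _REPORT_ROWS if k in mc}
        report["strains"][sid] = entry

    active = [
        sid for sid, t in tables.items()
        if not t.strain.is_control and report["strains"][sid]["co2_uptake"] > 0
    ]
    for i, a in enumerate(active):
        for b in active[:i] + active[i + 1:]:
            ua = report["strains"][a]["co2_uptake"]
            ub = report["strains"][b]["co2_uptake"]
            if ub > 0:
                report["comparisons"][f"co2_uptake_{a}_vs_{b}"] = ua / ub
    return report


def format_report(report: dict, ndigits: int = 2) -> str:
    """Human-readable report table in the published row order."""
    strains = list(report["strains"])
    lines = ["Rubisco-based CO2 capture analysis", ""]
    lines.append("Provenance: " + json.dumps(report["provenance"]))
    lines.append("")
    header = f"{'quantity':30s}" + "".join(f"{s:>12s}" for s in strains)
    lines.append(header)
    lines.append("-" * len(header))
    for key, nd in _REPORT_ROWS:
        row = f"{key:30s}"
        for s in strains:
            row += f"{round_half_away(report['strains'][s][key], nd):>12g}"
        lines.append(row)
    if report["comparisons"]:
        lines.append("")
        for name, fold in report["comparisons"].items():
            lines.append(f"{name}: {fold:.1f}-fold")
    return "\n".join(lines)
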