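"""Tabular schemas, configuration and the period report.

All data files are plain CSV/TSV with fixed, documented headers (UTF-8,
Unix newlines, decimal point), so reports are byte-identical across runs.

Schemas
-------
timeseries.csv : time_d, location, species, value, unit
    location in {broth, effluent, extract_solution}; unit in
    {gCOD_L, gCOD, g_L, mM}.  Broth/effluent rows are concentrations,
    extract_solution rows cumulative amounts (g COD).
periods.csv : period_id, phase, t_start_d, t_end_d, volume_L, HRT_d,
    OLR_gCOD_L_d, Q_feed_L_d, Q_effluent_L_d, Q_recycle_L_d,
    ethanol_cod_fraction, inner_diameter_m
studies.csv : label, u_m_d, A_transfer_m2, C_MCCA_undiss_gCOD_L, volume_L,
    C_MCC_broth_gCOD_L, HRT_d, observed_flux (optional)
otu_counts.tsv : OTU ids in the first column, sample ids as remaining
    headers; an optional ``taxonomy`` column is carried through.
sample_metadata.tsv : sample_id, day, productivity (blank for samples
    without productivity, e.g. inoculum/substrate).
performance.csv : one row per (period, species) plus lumped MCC rows.
correlations.csv : otu_id, taxonomy, r, p, significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .microbiome import OtuTable
from .pertraction import StudyRecord
from .rates import PeriodDefinition, PeriodPerformance
from .species import SpeciesRegistry, UnknownSpeciesError, default_registry, to_cod

__all__ = [
    "RunConfig",
    "SchemaError",
    "load_timeseries",
    "load_periods",
    "write_periods",
    "load_studies",
    "load_otu_table",
    "write_otu_table",
    "write_performance",
    "render_period_report",
    "load_config",
]

logger = logging.getLogger("mccflux")

_TIMESERIES_COLUMNS = ["time_d", "location", "species", "value", "unit"]
_LOCATIONS = {"broth", "effluent", "extract_solution"}
_UNITS = {"gCOD_L", "gCOD", "g_L", "mM"}


class SchemaError(ValueError):
    """Raised for malformed input tables, naming the offending row/column."""


def load_timeseries(
    path, registry: Optional[SpeciesRegistry] = None
) -> pd.DataFrame:
    """Read and normalise timeseries.csv to g COD values.

    Concentration rows (g_L, mM) are converted via the species registry to
    gCOD_L; amount rows must already be gCOD.  Unknown species/units and
    duplicate timestamps per (location, species) raise a
    :class:`SchemaError` naming the row.
    """
    reg = registry or default_registry()
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty timeseries input")
    missing = [c for c in _TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    values, units, canon = [], [], []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        if row["location"] not in _LOCATIONS:
            raise SchemaError(f"{path} row {rowno}: unknown location {row['location']!r}")
        if row["unit"] not in _UNITS:
            raise SchemaError(f"{path} row {rowno}: unknown unit {row['unit']!r}")
        try:
            species = reg.canonical_name(row["species"])
        except UnknownSpeciesError:
            raise SchemaError(
                f"{path} row {rowno}: unknown species {row['species']!r}"
            ) from None
        v = float(row["value"])
        if v < 0:
            raise SchemaError(f"{path} row {rowno}: negative value {v}")
        unit = row["unit"]
        if unit == "g_L":
            v, unit = to_cod(v, "g/L", species, reg), "gCOD_L"
        elif unit == "mM":
            v, unit = to_cod(v / 1000.0, "mol/L", species, reg), "gCOD_L"
        if row["location"] == "extract_solution" and unit != "gCOD":
            raise SchemaError(
                f"{path} row {rowno}: extract_solution rows must be amounts (gCOD)"
            )
        values.append(v)
        units.append(unit)
        canon.append(species)

    out = df.assign(species=canon, value=values, unit=units)
    dup = out.duplicated(subset=["time_d", "location", "species"], keep=False)
    if dup.any():
        first = out.index[dup][0] + 2
        raise SchemaError(
            f"{path} row {first}: duplicate timestamp for "
            f"({out.loc[out.index[dup][0], 'location']}, {out.loc[out.index[dup][0], 'species']})"
        )
    return out.sort_values(["time_d", "location", "species"], kind="stable").reset_index(drop=True)


_PERIOD_FIELDS = {
    "period_id": "period_id",
    "phase": "phase",
    "t_start_d": "t_start",
    "t_end_d": "t_end",
    "volume_L": "volume_l",
    "HRT_d": "hrt_d",
    "OLR_gCOD_L_d": "olr_gcod_l_d",
    "Q_feed_L_d": "q_feed_l_d",
    "Q_effluent_L_d": "q_effluent_l_d",
    "Q_recycle_L_d": "q_recycle_l_d",
    "ethanol_cod_fraction": "ethanol_cod_fraction",
    "inner_diameter_m": "inner_diameter_m",
}


def load_periods(path) -> list[PeriodDefinition]:
    df = pd.read_csv(path)
    missing = [c for c in _PERIOD_FIELDS if c not in df.columns and c not in ("phase", "ethanol_cod_fraction", "inner_diameter_m")]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    periods = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _PERIOD_FIELDS.items():
            if col in df.columns and not pd.isna(row[col]):
                val = row[col]
                kwargs[attr] = str(val) if attr in ("period_id", "phase") else float(val)
        periods.append(PeriodDefinition(**kwargs))
    return periods


def write_periods(periods: Sequence[PeriodDefinition], path) -> None:
    rows = [
        {col: getattr(p, attr) for col, attr in _PERIOD_FIELDS.items()}
        for p in periods
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


_STUDY_FIELDS = {
    "label": "label",
    "u_m_d": "u_m_d",
    "A_transfer_m2": "a_transfer_m2",
    "C_MCCA_undiss_gCOD_L": "c_mcca_undiss_gcod_l",
    "volume_L": "volume_l",
    "C_MCC_broth_gCOD_L": "c_mcc_broth_gcod_l",
    "HRT_d": "hrt_d",
    "observed_flux": "observed_flux",
}


def load_studies(path) -> list[StudyRecord]:
    df = pd.read_csv(path)
    required = [c for c in _STUDY_FIELDS if c != "observed_flux"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"label": str(row["label"])}
        for col, attr in _STUDY_FIELDS.items():
            if col == "label":
                continue
            if col in df.columns and not pd.isna(row[col]):
                kwargs[attr] = float(row[col])
            elif col == "observed_flux":
                kwargs[attr] = None
            else:
                kwargs[attr] = float("nan")
        records.append(StudyRecord(**kwargs))
    return records


def load_otu_table(counts_path, metadata_path=None) -> OtuTable:
    """Read an OTUs-x-samples TSV (plus optional sample metadata TSV)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"]
        df = df.drop(columns="taxonomy")
    counts = df.T.astype(int)  # stored OTUs x samples; in-memory samples x OTUs
    counts.index.name = None
    counts.columns.name = None
    metadata = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t")
        if "sample_id" not in meta.columns:
            raise SchemaError(f"{metadata_path}: missing sample_id column")
        metadata = meta.set_index("sample_id")
    return OtuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, counts_path, metadata_path=None) -> None:
    out = table.counts.T.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.index.name = "otu_id"
    out.to_csv(counts_path, sep="\t", lineterminator="\n")
    if metadata_path is not None and table.metadata is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t", lineterminator="\n")


_PERFORMANCE_COLUMNS = [
    "period_id",
    "phase",
    "species",
    "extraction_gCOD_d",
    "washout_gCOD_d",
    "production_gCOD_d",
    "productivity_gCOD_L_d",
    "flux_gCOD_m2_d",
    "specificity",
]


def performance_frame(performances: Sequence[PeriodPerformance]) -> pd.DataFrame:
    """Long-format performance table: per-species rows plus lumped MCC rows."""
    rows = []
    for perf in sorted(performances, key=lambda p: p.t_start):
        for s in perf.production:
            rows.append(
                dict(
                    period_id=perf.period_id,
                    phase=perf.phase,
                    species=s,
                    extraction_gCOD_d=perf.extraction[s],
                    washout_gCOD_d=perf.washout[s],
                    production_gCOD_d=perf.production[s],
                    productivity_gCOD_L_d=perf.productivity[s],
                    flux_gCOD_m2_d=perf.flux[s],
                    specificity=perf.specificity[s],
                )
            )
        rows.append(
            dict(
                period_id=perf.period_id,
                phase=perf.phase,
                species="MCC",
                extraction_gCOD_d=np.nan,
                washout_gCOD_d=np.nan,
                production_gCOD_d=perf.mcc_production,
                productivity_gCOD_L_d=perf.mcc_productivity,
                flux_gCOD_m2_d=perf.mcc_flux,
                specificity=np.nan,
            )
        )
    return pd.DataFrame(rows, columns=_PERFORMANCE_COLUMNS)


def write_performance(performances: Sequence[PeriodPerformance], path) -> None:
    performance_frame(performances).to_csv(path, index=False, lineterminator="\n")


_REPORT_COLUMNS = [
    "phase",
    "period_id",
    "OLR_gCOD_L_d",
    "HRT_d",
    "Q_recycle_L_d",
    "MCC_productivity_gCOD_L_d",
    "MCC_flux_gCOD_m2_d",
    "MCC_yield_pct",
    "specificity_C6_pct",
    "specificity_C8_pct",
    "C8_C6_ratio",
]


def render_period_report(
    performances: Sequence[PeriodPerformance],
) -> tuple[pd.DataFrame, str]:
    """Per-period summary table in reporting style, plus a text rendering.

    Rounding follows the reporting convention: rates/ratios to 1 decimal
    place, percentages to integers (full precision is retained in
    performance.csv).  Rows are ordered by period start time.
    """
    rows = []
    for perf in sorted(performances, key=lambda p: p.t_start):
        spec_c6 = perf.specificity.get("n-caproate", float("nan"))
        spec_c8 = perf.specificity.get("n-caprylate", float("nan"))
        rows.append(
            {
                "phase": perf.phase,
                "period_id": perf.period_id,
                "OLR_gCOD_L_d": round(perf.olr_gcod_l_d, 1),
                "HRT_d": round(perf.hrt_d, 1),
                "Q_recycle_L_d": round(perf.q_recycle_l_d, 1),
                "MCC_productivity_gCOD_L_d": round(perf.mcc_productivity, 1),
                "MCC_flux_gCOD_m2_d": round(perf.mcc_flux, 1),
                "MCC_yield_pct": (
                    int(round(perf.mcc_yield * 100)) if perf.mcc_yield is not None else None
                ),
                "specificity_C6_pct": (
                    int(round(spec_c6 * 100)) if np.isfinite(spec_c6) else None
                ),
                "specificity_C8_pct": (
                    int(round(spec_c8 * 100)) if np.isfinite(spec_c8) else None
                ),
                "C8_C6_ratio": (
                    round(perf.product_ratio_c8_c6, 1)
                    if perf.product_ratio_c8_c6 is not None
                    else None
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    lines = ["Period performance summary (COD basis)", "=" * 40]
    for r in rows:
        lines.append(
            f"{r['period_id']} (phase {r['phase']}): OLR {r['OLR_gCOD_L_d']} g COD/L-d, "
            f"MCC productivity {r['MCC_productivity_gCOD_L_d']} g COD/L-d, "
            f"yield {r['MCC_yield_pct']}%, "
            f"specificity C6/C8 {r['specificity_C6_pct']}%/{r['specificity_C8_pct']}%, "
            f"C8:C6 ratio {r['C8_C6_ratio']}"
        )
    if not rows:
        lines.append("(no periods)")
    return frame, "\n".join(lines)


_CONFIG_KEYS = {
    "timeseries",
    "periods",
    "studies",
    "otu_counts",
    "sample_metadata",
    "species_registry",
    "a_transfer_m2",
    "a_cross_m2",
    "ph",
    "shannon_base",
    "abundance_threshold",
    "alpha",
    "output_dir",
    "seed",
}


@dataclass
class RunConfig:
    """End-user run configuration (paths + analysis options)."""

    timeseries: Optional[Path] = None
    periods: Optional[Path] = None
    studies: Optional[Path] = None
    otu_counts: Optional[Path] = None
    sample_metadata: Optional[Path] = None
    species_registry: Optional[Path] = None
    a_transfer_m2: float = 1.4
    a_cross_m2: float = 1.56e-3
    ph: float = 5.2
    shannon_base: float = 2.0
    abundance_threshold: float = 0.01
    alpha: float = 0.05
    output_dir: Path = field(default_factory=lambda: Path("."))
    seed: int = 0

    def registry(self) -> SpeciesRegistry:
        if self.species_registry is not None:
            return SpeciesRegistry.from_csv(self.species_registry)
        return default_registry()


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    path_keys = {
        "timeseries",
        "periods",
        "studies",
        "otu_counts",
        "sample_metadata",
        "species_registry",
    }
    kwargs = {}
    base = Path(path).parent
    for key, value in raw.items():
        if key in path_keys and value is not None:
            p = Path(value)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise SchemaError(f"{path}: referenced path does not exist: {value}")
            kwargs[key] = p
        elif key == "output_dir":
            kwargs[key] = Path(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
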