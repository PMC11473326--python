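"""Phenotype-table ingestion and simulation-config loading.

The interchange format is a long-format UTF-8 CSV with a header row and
columns ``line,condition,block,trait,value`` ("." decimal separator).
Missing phenotypes may be written as an empty field or ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SimulationConfig, TraitSpec

__all__ = [
    "ingest_phenotypes",
    "write_phenotypes",
    "load_simulation_config",
    "combined_correlation_table",
]

REQUIRED_COLUMNS = ("line", "condition", "block", "trait", "value")


def ingest_phenotypes(path) -> pd.DataFrame:
    """Read and validate a long-format phenotype CSV.

    Rejects missing columns, empty tables, more than two conditions and
    duplicated (line, condition, block, trait) records (reported with
    their 1-based data row numbers).  Non-numeric values parse to missing
    and are tolerated.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"line": str, "condition": str, "block": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    if table.empty:
        raise ValueError(f"{path}: no data rows")
    table["value"] = pd.to_numeric(table["value"], errors="coerce")
    key = ["line", "condition", "block", "trait"]
    dup = table.duplicated(subset=key, keep=False)
    if dup.any():
        rows = (table.index[dup] + 1).tolist()
        raise ValueError(f"{path}: duplicated records at data row(s) {rows[:10]}")
    n_cond = table["condition"].nunique()
    if n_cond > 2:
        raise ValueError(
            f"{path}: {n_cond} conditions found; the design has exactly two"
        )
    return table[list(REQUIRED_COLUMNS)]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from JSON or YAML.

    The document mirrors the dataclass: top-level design fields plus a
    ``traits`` list of trait-spec mappings.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    traits = tuple(TraitSpec(**spec) for spec in doc.pop("traits"))
    if "conditions" in doc:
        doc["conditions"] = tuple(doc["conditions"])
    config = SimulationConfig(traits=traits, **doc)
    config.validate()
    return config


def combined_correlation_table(
    pearson_NAP, pearson_AP, spearman_diag: pd.Series
) -> pd.DataFrame:
    """Single matrix mimicking the panel report's correlation layout.

    Stress-condition Pearson coefficients below the diagonal, control
    above, and the cross-condition Spearman coefficient of each trait on
    the diagonal.
    """
    traits = pearson_NAP.labels
    if pearson_AP.labels != traits:
        raise ValueError("trait order differs between conditions")
    out = pd.DataFrame(0.0, index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i > j:
                out.iloc[i, j] = pearson_NAP.estimates.iloc[i, j]
            elif i < j:
                out.iloc[i, j] = pearson_AP.estimates.iloc[i, j]
            else:
                out.iloc[i, j] = spearman_diag.get(a, float("nan"))
    return out
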