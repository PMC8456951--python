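"""Table readers/writers and the run configuration.

Canonical on-disk dialect is TSV (UTF-8, '.' decimal, ISO-8601 dates);
CSV is accepted on read.  Count tables need ``sample_id`` and ``date``
columns; environment tables need ``sample_id`` plus covariate columns.
Output files carry a comment header embedding the package version and
the configuration hash so results are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import CompositionMatrix
from .preprocess import CountTable

__all__ = [
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "read_env_table",
    "write_env_table",
    "read_composition_matrix",
    "write_composition_matrix",
    "write_table",
]

_SEP = {".tsv": "\t", ".txt": "\t", ".csv": ","}


def _sep_for(path) -> str:
    return _SEP.get(Path(path).suffix.lower(), "\t")


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s): {dup}")
    return df.set_index("sample_id")


def read_count_table(path) -> CountTable:
    """Read an oligotype count table (sample_id, date, one column per part)."""
    df = _read_table(path)
    if "date" not in df.columns:
        raise ValueError(f"{path}: missing required 'date' column")
    dates = pd.to_datetime(df.pop("date"))
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(f"{path}: malformed numeric cell at row {row!r}, column {col!r}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValueError(f"{path}: negative count at row {row!r}, column {col!r}")
        df[col] = vals
    return CountTable(df, dates)


def _header(config_hash: str | None) -> str:
    h = f" config={config_hash}" if config_hash else ""
    return f"# oligocoda {__version__}{h}\n"


def write_table(df: pd.DataFrame, path, config_hash: str | None = None,
                index_label: str = "sample_id") -> None:
    """Write any indexed table as TSV with the provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep=_sep_for(path), index_label=index_label)


def write_count_table(table: CountTable, path, config_hash: str | None = None) -> None:
    df = table.counts.copy()
    df.insert(0, "date", table.dates.dt.strftime("%Y-%m-%d"))
    write_table(df, path, config_hash)


def read_env_table(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read covariates; returns (table, dates or None if no date column)."""
    df = _read_table(path)
    dates = pd.to_datetime(df.pop("date")) if "date" in df.columns else None
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df, dates


def write_env_table(env: pd.DataFrame, path, dates: pd.Series | None = None,
                    config_hash: str | None = None) -> None:
    df = env.copy()
    if dates is not None:
        df.insert(0, "date", pd.to_datetime(dates).dt.strftime("%Y-%m-%d"))
    write_table(df, path, config_hash)


def write_composition_matrix(X: CompositionMatrix, path,
                             config_hash: str | None = None) -> None:
    df = X.data.copy()
    df.insert(0, "date", X.dates.dt.strftime("%Y-%m-%d"))
    write_table(df, path, config_hash)


def read_composition_matrix(path) -> CompositionMatrix:
    df = _read_table(path)
    dates = pd.to_datetime(df.pop("date"))
    return CompositionMatrix(df.astype(float), dates)


@dataclass
class RunConfig:
    """Full-pipeline configuration; serializable and hashable for provenance."""

    counts_path: str = ""
    env_path: str = ""
    daily_light_path: str | None = None
    out_dir: str = "results"
    keep_parts: tuple[str, ...] = ("O1", "O2", "O3", "O4", "O5", "O6")
    min_reads: int = 15
    imputation_strength: str | float = "sqrt"
    sbp_source: str = "builtin:mvco"  # or a TSV path, or "from-variation"
    sbp_linkage: str = "ward"
    alpha: float = 0.05
    temperature_only: bool = True  # also fit the restricted model
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "keep_parts" in raw:
            raw["keep_parts"] = tuple(raw["keep_parts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["keep_parts"] = list(d["keep_parts"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hash(self) -> str:
        d = asdict(self)
        d["keep_parts"] = list(d["keep_parts"])
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
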