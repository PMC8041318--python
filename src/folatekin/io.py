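"""Table readers/writers and JSON reporting shared by all pipeline stages.

All tables are comma-separated UTF-8 text with a header row and '.' decimal;
no locale inference.  Every reader validates the schema up front and fails
with a message naming the offending column.  Reports are JSON with the seed
and input provenance (SHA-256 of each input file) embedded, so reruns on
identical inputs yield identical payloads.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from importlib import metadata
from pathlib import Path

import pandas as pd

from .decay import DecaySeries
from .errors import InputError
from .mechanism import RateDataset

__all__ = [
    "read_table",
    "read_rate_table",
    "read_decay_table",
    "read_fraction_table",
    "read_displacement_table",
    "read_combination_table",
    "file_sha256",
    "build_report",
    "write_report",
]

RATE_COLUMNS = ("substrate_uM", "inhibitor_uM", "dump_uM", "rate")
DECAY_COLUMNS = ("time_min", "concentration_uM", "replicate")
FRACTION_COLUMNS = ("fraction", "mass_ng", "temperature_C")
DISPLACEMENT_COLUMNS = ("label", "displacement_fraction", "competitor_uM")
COMBINATION_COLUMNS = (
    "cell_line", "drug_a", "dose_a", "drug_b", "dose_b",
    "inh_a_pct", "inh_b_pct", "inh_combined_pct",
)

_NUMERIC = {
    "substrate_uM", "inhibitor_uM", "dump_uM", "rate",
    "time_min", "concentration_uM",
    "mass_ng", "temperature_C",
    "displacement_fraction", "competitor_uM",
    "dose_a", "dose_b", "inh_a_pct", "inh_b_pct", "inh_combined_pct",
}


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a CSV and validate presence and numeric type of required columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    for col in required_columns:
        if col in _NUMERIC:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise InputError(
                    f"{path.name}: column {col!r} is not numeric: {exc}"
                )
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()
                raise InputError(
                    f"{path.name}: column {col!r} has missing values at rows {rows}"
                )
    return df


def read_rate_table(path) -> RateDataset:
    return RateDataset(read_table(path, RATE_COLUMNS))


def read_decay_table(path) -> DecaySeries:
    return DecaySeries(read_table(path, DECAY_COLUMNS))


def read_fraction_table(path) -> pd.DataFrame:
    return read_table(path, FRACTION_COLUMNS)


def read_displacement_table(path) -> pd.DataFrame:
    return read_table(path, DISPLACEMENT_COLUMNS)


def read_combination_table(path) -> pd.DataFrame:
    return read_table(path, COMBINATION_COLUMNS)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return None
        return obj
    if hasattr(obj, "item"):  # numpy scalars
        return _jsonable(obj.item())
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def build_report(stage: str, results, inputs=None, seed=None) -> dict:
    """Assemble a report payload with provenance for one pipeline stage."""
    try:
        version = metadata.version("folatekin")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {
        "stage": stage,
        "version": version,
        "seed": seed,
        "inputs": {
            str(name): file_sha256(p) for name, p in (inputs or {}).items()
        },
        "results": _jsonable(results),
    }


def write_report(report: dict, path=None) -> str:
    """Serialize a report to JSON, optionally writing it to ``path``."""
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
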