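"""CSV schema and config plumbing shared by the command-line tools.

Quadrat censuses have no standard interchange format, so the package uses
a plain long-format CSV, one row per quadrat × census interval:

    shore,quadrat,period,T_days,N_start,N_end,operc_area,basal_area,dead_cover

Header required, UTF-8, '.' decimal.  Numbers are written with
shortest-round-trip precision so a write/read cycle is lossless.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .inference import QuadratObservation

__all__ = [
    "SCHEMA",
    "SchemaError",
    "read_observations",
    "write_observations",
    "write_table",
    "resolve_config",
]

logger = logging.getLogger("recruitmap")

SCHEMA = (
    "shore", "quadrat", "period", "T_days", "N_start", "N_end",
    "operc_area", "basal_area", "dead_cover",
)

_STRING_COLS = ("shore", "quadrat", "period")
_FLOAT_COLS = tuple(c for c in SCHEMA if c not in _STRING_COLS)


class SchemaError(ValueError):
    """Input table does not match the observation schema."""


def read_observations(path: str | Path) -> list[QuadratObservation]:
    """Read and validate a long-format census CSV.

    Raises :class:`SchemaError` naming any missing column; cell-level
    problems are collected and reported together with 1-based data line
    numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[QuadratObservation] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        vals = {}
        ok = True
        for col in _FLOAT_COLS:
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except ValueError:
                errors.append(f"line {line}: non-numeric {col}={raw!r}")
                ok = False
        if not ok:
            continue
        if any(math.isnan(vals[c]) for c in ("T_days", "N_start", "N_end")):
            errors.append(f"line {line}: NaN in a required numeric field")
            continue
        try:
            records.append(QuadratObservation(
                shore=getattr(row, "shore"), quadrat=getattr(row, "quadrat"),
                period=getattr(row, "period"), **vals,
            ))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n  "
                          + "\n  ".join(errors))
    return records


def _observation_frame(records: Iterable[QuadratObservation]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in SCHEMA} for r in records]
    df = pd.DataFrame(rows, columns=SCHEMA)
    # deterministic row order: shore, quadrat, then period in first-seen order
    period_order = {p: i for i, p in enumerate(dict.fromkeys(df["period"]))}
    df = df.assign(_p=df["period"].map(period_order))
    df = df.sort_values(["shore", "quadrat", "_p"], kind="stable")
    return df.drop(columns="_p").reset_index(drop=True)


def write_observations(records: Iterable[QuadratObservation],
                       path: str | Path) -> None:
    """Write observations as schema CSV in deterministic order."""
    write_table(_observation_frame(records), path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy table as CSV with round-trip-faithful floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=None)  # str() = shortest repr
    logger.info("wrote %d rows to %s", len(df), path)


def resolve_config(
    flags: Mapping[str, object],
    config_file: str | Path | None,
    allowed: Sequence[str],
) -> dict:
    """Merge a YAML/JSON config file with command-line flags.

    Flag values (non-None) override file values; keys outside ``allowed``
    are rejected.  The resolved mapping is echoed to the log so every run
    is reproducible from its log line plus the seed.
    """
    resolved: dict = {}
    if config_file is not None:
        with open(config_file, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{config_file}: config must be a mapping")
        unknown = sorted(set(loaded) - set(allowed))
        if unknown:
            raise ValueError(
                f"{config_file}: unknown config key(s): {', '.join(unknown)}"
            )
        resolved.update(loaded)
    unknown = sorted(set(flags) - set(allowed))
    if unknown:
        raise ValueError(f"unknown option(s): {', '.join(unknown)}")
    for key, val in flags.items():
        if val is not None:
            resolved[key] = val
    logger.info("resolved config: %s", resolved)
    return resolved
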