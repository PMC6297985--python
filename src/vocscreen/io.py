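"""Delimited-text readers and writers for the package's table formats.

All tables are tab-separated text with an explicit header row; units are
embedded in column names where they are not fixed by the schema.

* concentration series: ``cuvette_id  compound_id  time_s  value``
* multiplexed log:      ``time_s  active_cuvette  channel  value``
* inlet table:          ``time_s  channel  value``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .cuvette import ConcentrationSeries
from .errors import SchemaError
from .signals import LOG_COLUMNS, MultiplexedLog

SERIES_COLUMNS = ("cuvette_id", "compound_id", "time_s", "value")
INLET_COLUMNS = ("time_s", "channel", "value")

__all__ = [
    "read_table",
    "read_concentration_series",
    "write_concentration_series",
    "read_multiplexed_log",
    "write_multiplexed_log",
    "read_inlet_table",
    "write_inlet_table",
    "write_manifest",
]


def read_table(path, required_columns: Tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse delimited text ({exc})") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    return df


def read_concentration_series(path) -> List[ConcentrationSeries]:
    """Read one or more series (grouped by cuvette and compound)."""
    df = read_table(path, SERIES_COLUMNS)
    out = []
    for (cid, compound), group in df.groupby(["cuvette_id", "compound_id"],
                                             sort=True):
        group = group.sort_values("time_s", kind="stable")
        out.append(ConcentrationSeries(str(cid), str(compound),
                                       group["time_s"].to_numpy(float),
                                       group["value"].to_numpy(float)))
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def write_concentration_series(series: Iterable[ConcentrationSeries], path) -> None:
    frames = [pd.DataFrame({"cuvette_id": s.cuvette_id,
                            "compound_id": s.compound_id,
                            "time_s": s.timestamps,
                            "value": s.values})
              for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_multiplexed_log(path) -> MultiplexedLog:
    return MultiplexedLog(read_table(path, LOG_COLUMNS))


def write_multiplexed_log(log: MultiplexedLog, path) -> None:
    log.records.to_csv(path, sep="\t", index=False)


def read_inlet_table(path) -> pd.DataFrame:
    return read_table(path, INLET_COLUMNS)


def write_inlet_table(inlet: pd.DataFrame, path) -> None:
    inlet.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: Dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
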