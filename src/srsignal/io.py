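"""Readers and writers for the two SRS table dialects.

JADER dialect: comma-separated text in CP932 (the Shift-JIS family encoding
PMDA distributes), tables ``demo``/``drug``/``reac``/``hist``, case key
``識別番号``.  FAERS dialect: ``$``-delimited ASCII with a header line,
tables ``demo``/``drug``/``reac``/``ther``/``outc`` keyed by ``primaryid``/
``caseid``.

All fields are kept as text; parsing into typed values happens lazily in
:mod:`srsignal.cases`.  The line-level loops here exist to honour the error
contracts (undecodable bytes and header/row arity mismatches must be reported
with file and line number); the formats themselves are trivial.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SRSFormatError",
    "read_jader_tables",
    "read_faers_tables",
    "write_jader_tables",
    "write_faers_tables",
    "dedup_faers",
    "JADER_TABLES",
    "FAERS_TABLES",
]

logger = logging.getLogger(__name__)

JADER_TABLES = ("demo", "drug", "reac", "hist")
FAERS_TABLES = ("demo", "drug", "reac", "ther", "outc")

JADER_ENCODING = "cp932"


class SRSFormatError(ValueError):
    """Malformed SRS input (encoding, arity, or missing table)."""


def _require_demo(paths: Mapping[str, "Path | str"]) -> None:
    if "demo" not in paths:
        raise SRSFormatError("missing required table: demo")


def read_jader_tables(paths: Mapping[str, "Path | str"]) -> dict[str, pd.DataFrame]:
    """Read JADER-dialect CSV tables (CP932) into string DataFrames.

    Row counts are preserved exactly; no type coercion is applied.
    """
    _require_demo(paths)
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise SRSFormatError(f"missing required table: {name} ({path})")
        lines: list[str] = []
        with open(path, "rb") as fh:
            for lineno, raw in enumerate(fh, start=1):
                try:
                    lines.append(raw.decode(JADER_ENCODING))
                except UnicodeDecodeError as exc:
                    raise SRSFormatError(
                        f"{path}: line {lineno}: undecodable {JADER_ENCODING} bytes"
                    ) from exc
        rows = list(csv.reader(_io.StringIO("".join(lines))))
        if not rows:
            tables[name] = pd.DataFrame()
            continue
        header, body = rows[0], rows[1:]
        tables[name] = pd.DataFrame(body, columns=header, dtype=str)
    return tables


def read_faers_tables(paths: Mapping[str, "Path | str"]) -> dict[str, pd.DataFrame]:
    """Read FAERS-dialect ``$``-delimited ASCII tables into string DataFrames.

    Fields are split positionally on ``$`` against the header; a row whose
    field count differs from the header's raises with the offending line
    number.  Trailing empty fields are preserved as empty strings.
    """
    _require_demo(paths)
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise SRSFormatError(f"missing required table: {name} ({path})")
        with open(path, "r", encoding="ascii") as fh:
            header_line = fh.readline()
            if not header_line:
                tables[name] = pd.DataFrame()
                continue
            header = header_line.rstrip("\r\n").split("$")
            body: list[list[str]] = []
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\r\n").split("$")
                if len(fields) != len(header):
                    raise SRSFormatError(
                        f"{path}: line {lineno}: expected {len(header)} fields, "
                        f"got {len(fields)}"
                    )
                body.append(fields)
        tables[name] = pd.DataFrame(body, columns=header, dtype=str)
    return tables


def write_jader_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: "Path | str"
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, encoding=JADER_ENCODING, lineterminator="\n")
        written[name] = path
    return written


def write_faers_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: "Path | str"
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out_dir / f"{name.upper()}.txt"
        with open(path, "w", encoding="ascii", newline="") as fh:
            fh.write("$".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join("" if v is None else str(v) for v in row) + "\n")
        written[name] = path
    return written


def dedup_faers(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep, per FAERS case, the row with the highest case version number.

    Missing/unparseable ``caseversion`` is treated as version 0.  Ties on the
    version are broken by the larger ``primaryid`` (numerically where
    possible), so repeated submissions of the same version resolve to the
    latest report identifier.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    version = pd.to_numeric(work.get("caseversion"), errors="coerce").fillna(0)
    primary = pd.to_numeric(work.get("primaryid"), errors="coerce").fillna(-1)
    order = work.assign(_ver=version.to_numpy(), _pid=primary.to_numpy()).sort_values(
        ["_ver", "_pid"], kind="stable"
    )
    kept = order.drop_duplicates(subset="caseid", keep="last")
    n_dropped = len(work) - len(kept)
    if n_dropped:
        logger.info("dedup_faers: dropped %d duplicate case version(s)", n_dropped)
    return (
        kept.drop(columns=["_ver", "_pid"]).sort_index().reset_index(drop=True)
    )
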