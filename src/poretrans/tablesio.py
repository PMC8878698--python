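"""CSV/JSON persistence with exact round-trips and a streaming reader.

CSV dialect: comma-separated, UTF-8, header row, "." decimal point.
Floats are rendered with Python's shortest round-trip representation, so a
write-then-read cycle reproduces every value bit-exactly; integers stay
integers.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Any, Iterator, Sequence

import pandas as pd


class TableFormatError(ValueError):
    """Malformed table file: carries the offending line or column."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr() is the shortest representation that round-trips a float exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def stream_rows(path: str | Path, required: Sequence[str] | None = None) -> Iterator[dict[str, str]]:
    """Iterate CSV rows one at a time with a bounded working set.

    Values are returned as strings; the caller converts what it needs.
    Malformed rows raise :class:`TableFormatError` with their line number.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file")
        if required:
            missing = [c for c in required if c not in reader.fieldnames]
            if missing:
                raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        ncols = len(reader.fieldnames)
        for row in reader:
            if None in row or any(v is None for v in row.values()):
                raise TableFormatError(
                    f"{path}: line {reader.line_num}: expected {ncols} fields"
                )
            yield row


def write_json(obj: Any, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping, for manifests."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]
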