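"""Tabular readers/writers and run configuration for the command-line tool.

Encoding is fixed to UTF-8 in and out (a UTF-8 BOM is tolerated on input);
files that do not decode as UTF-8 are rejected with a clear error rather
than decoded by guesswork.  All writes are atomic — content goes to a
temporary file in the target directory which is then renamed — so a failed
run never leaves a partial output behind.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .preprocess import RawEntry

__all__ = ["DataError", "RunConfig", "read_input_table", "atomic_write_text", "write_frame"]


class DataError(Exception):
    """A content-level problem in user-supplied data (exit code 2)."""


@dataclass
class RunConfig:
    """Resolved configuration of one standardization run."""

    input_path: Path
    output_path: Path
    atc_dict_path: Path
    rad_path: Path
    stoplist_path: Path | None = None
    input_column_name: str | None = None  # default: first column
    delimiter: str = ","
    joiner: str = ", "
    strict_codes: bool = False
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if not self.joiner:
            raise ValueError("joiner must be non-empty")
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")


def read_input_table(
    path: str | Path, column: str | None = None, delimiter: str = ","
) -> tuple[list[RawEntry], str]:
    """Read the free-text column of a delimited table into raw entries.

    Returns the entries (ids assigned positionally: E00001, …) and the name
    of the column used.  ``column=None`` selects the first column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(
            path, sep=delimiter, encoding="utf-8-sig", dtype=str, keep_default_na=False
        )
    except UnicodeDecodeError as exc:
        raise DataError(
            f"{path} is not valid UTF-8 (re-encode the file; Latin-1 is not guessed): {exc}"
        ) from None
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: no columns found (empty file?)") from None
    if column is None:
        column = str(frame.columns[0])
    if column not in frame.columns:
        raise DataError(
            f"{path}: column {column!r} not found; available columns: "
            + ", ".join(map(str, frame.columns))
        )
    entries = [
        RawEntry(entry_id=f"E{i + 1:05d}", text=text)
        for i, text in enumerate(frame[column].tolist())
    ]
    return entries, column


def atomic_write_text(path: str | Path, content: str) -> None:
    """Write text via a temp file + rename in the destination directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_frame(frame: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Atomically write a DataFrame as a UTF-8 delimited file."""
    atomic_write_text(path, frame.to_csv(index=False, sep=delimiter))
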