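"""Deterministic tabular output.

All commands emit RFC-4180 CSV (UTF-8, '.' decimal, header row) with a
documented, fixed column order and floats at 10 significant digits, so
identical inputs and seed produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd

__all__ = ["write_table", "format_table"]

FLOAT_FORMAT = "%.10g"


def format_table(
    records: pd.DataFrame | Sequence[Mapping[str, object]],
    columns: Sequence[str] | None = None,
) -> str:
    """Render records as a deterministic CSV string."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame.from_records(list(records), columns=columns)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return buf.getvalue()


def write_table(
    records: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write records to ``path`` as CSV; empty input yields a header-only
    file (``columns`` then being required to know the header)."""
    out = Path(path)
    text = format_table(records, columns)
    out.write_text(text, encoding="utf-8")
    return out
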