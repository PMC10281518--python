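"""Well-name conventions for multiwell plates.

Wells are addressed by a row letter (``A``..) and a 1-based column number,
formatted with a zero-padded two-digit column: ``"A01"``, ``"P24"``.
Internally the package uses 0-based ``(row, col)`` indices with the origin
at the top-left well (A1).
"""

from __future__ import annotations

import re
import string

_WELL_RE = re.compile(r"^([A-Z])(\d{2,3})$")


def well_name(row: int, col: int) -> str:
    """Format 0-based (row, col) indices as a canonical well name.

    >>> well_name(0, 0)
    'A01'
    >>> well_name(15, 23)
    'P24'
    """
    if not (0 <= row < 26):
        raise ValueError(f"row index {row} out of range [0, 26)")
    if col < 0:
        raise ValueError(f"column index {col} must be non-negative")
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """Parse a well name into 0-based (row, col) indices.

    Raises ``ValueError`` for anything that is not a letter followed by a
    zero-padded column number.
    """
    m = _WELL_RE.match(name.strip().upper())
    if m is None:
        raise ValueError(f"malformed well name: {name!r}")
    row = string.ascii_uppercase.index(m.group(1))
    col = int(m.group(2)) - 1
    if col < 0:
        raise ValueError(f"malformed well name: {name!r} (column must be >= 1)")
    return row, col


def check_well(name: str, n_rows: int, n_cols: int) -> tuple[int, int]:
    """Parse and bounds-check a well name against a plate geometry."""
    row, col = parse_well(name)
    if row >= n_rows or col >= n_cols:
        raise ValueError(
            f"well {name!r} outside a {n_rows}x{n_cols} plate"
        )
    return row, col


def all_wells(n_rows: int, n_cols: int) -> list[str]:
    """All well names of a plate in row-major order."""
    return [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]
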