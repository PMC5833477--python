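"""384-well plate coordinates and platemap I/O.

Well ids follow the letter-row + two-digit-column convention (A01..P24 for
384-well format). Row indices are 0-based internally and serialized 1-based.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

ROWS_384 = "ABCDEFGHIJKLMNOP"
N_COLS_384 = 24

PLATEMAP_COLUMNS = ["well", "role", "compound", "dose_uM"]

#: roles a platemap may assign to a well
KNOWN_ROLES = {"sample", "dmso", "deab", "lipid", "sirna_control", "empty"}

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")


class PlatemapError(ValueError):
    """Raised for malformed platemap files or well ids."""


def well_names_384() -> list[str]:
    """All 384 well ids in row-major order (A01..A24, B01.., P24)."""
    return [f"{r}{c:02d}" for r in ROWS_384 for c in range(1, N_COLS_384 + 1)]


def validate_well(well: str) -> tuple[int, int]:
    """Validate a 384-format well id, returning 0-based (row, col).

    Raises :class:`PlatemapError` for anything outside A01..P24.
    """
    m = _WELL_RE.match(well.strip())
    if not m:
        raise PlatemapError(f"malformed well id {well!r} (expected e.g. 'B02')")
    row = ROWS_384.index(m.group(1))
    col = int(m.group(2))
    if not 1 <= col <= N_COLS_384:
        raise PlatemapError(f"well {well!r}: column out of 384-well range 01..24")
    return row, col - 1


def load_platemap(path: str | Path) -> pd.DataFrame:
    """Read a platemap CSV with header ``well,role,compound,dose_uM``.

    Returns a DataFrame indexed by well id. Malformed well ids, duplicate
    wells, unknown roles and missing columns raise :class:`PlatemapError`
    with the offending line number.
    """
    df = pd.read_csv(path, comment="#", dtype={"well": str, "role": str, "compound": str})
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlatemapError(f"platemap {path}: missing columns {missing}")
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        well = str(row["well"]).strip()
        try:
            validate_well(well)
        except PlatemapError as e:
            raise PlatemapError(f"platemap {path} line {line}: {e}") from None
        if well in seen:
            raise PlatemapError(f"platemap {path} line {line}: duplicate well {well!r}")
        seen.add(well)
        role = str(row["role"]).strip()
        if role not in KNOWN_ROLES:
            raise PlatemapError(
                f"platemap {path} line {line}: unknown role {role!r} "
                f"(known: {sorted(KNOWN_ROLES)})"
            )
    out = df.copy()
    out["well"] = out["well"].str.strip()
    out["role"] = out["role"].str.strip()
    out["dose_uM"] = pd.to_numeric(out["dose_uM"], errors="coerce").fillna(0.0)
    return out.set_index("well", drop=False)
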