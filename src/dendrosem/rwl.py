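"""Reader/writer for Tucson (decadal) RWL ring-width files.

The interchange format used by the ITRDB: each line carries a series id,
the calendar year of the first value on the line, and up to ten values,
lines advancing by decade. A terminator of 999 marks the series end and
implies 0.01 mm units; -9999 implies 0.001 mm units.
"""

from __future__ import annotations

from pathlib import Path

from .rings import TreeRingSeries

__all__ = ["read_rwl", "write_rwl", "RwlParseError"]


class RwlParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


_SCALE = {999: 0.01, -9999: 0.001}


def read_rwl(path: str | Path) -> list[TreeRingSeries]:
    """Parse a Tucson decadal file into a list of ring-width series (mm)."""
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise RwlParseError("expected series id, year and values", line_no)
            try:
                year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RwlParseError(f"non-integer field ({exc})", line_no) from None
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            prev = raw[sid]
            if prev:
                last_year, last_vals, _ = prev[-1]
                expected = last_year + len(last_vals)
                # subsequent lines start at decade boundaries
                if year != expected:
                    raise RwlParseError(
                        f"series {sid}: expected decade starting {expected}, got {year}",
                        line_no,
                    )
            raw[sid].append((year, values, line_no))

    out = []
    for sid in order:
        blocks = raw[sid]
        last_line = blocks[-1][2]
        flat = [v for _, vals, _ in blocks for v in vals]
        if not flat or flat[-1] not in _SCALE:
            raise RwlParseError(f"series {sid} lacks a 999/-9999 terminator", last_line)
        terminator = flat[-1]
        values = flat[:-1]
        # a value of 999 inside a -9999 series is data (0.999 mm); a -9999
        # anywhere except the end, or any other negative, is malformed
        if any(v < 0 for v in values):
            raise RwlParseError(
                f"series {sid}: negative or misplaced terminator value", last_line
            )
        if not values:
            raise RwlParseError(f"series {sid} is empty", blocks[0][2])
        scale = _SCALE[terminator]
        out.append(
            TreeRingSeries(
                tree_id=sid,
                first_year=blocks[0][0],
                widths=[v * scale for v in values],
            )
        )
    return out


def write_rwl(series: list[TreeRingSeries], path: str | Path, precision: float = 0.001) -> None:
    """Write series in Tucson decadal layout.

    precision 0.001 mm uses the -9999 terminator, 0.01 mm uses 999.
    Widths are rounded to the chosen precision on output.
    """
    if precision == 0.001:
        terminator = -9999
    elif precision == 0.01:
        terminator = 999
    else:
        raise ValueError("precision must be 0.001 or 0.01")
    lines = []
    for s in series:
        sid = str(s.tree_id)[:8]
        vals = [int(round(w / precision)) for w in s.widths] + [terminator]
        year = s.first_year
        i = 0
        while i < len(vals):
            # each line runs to the end of its decade (first may be partial)
            n = 10 - (year % 10)
            chunk = vals[i : i + n]
            fields = "".join(f"{v:6d}" for v in chunk)
            lines.append(f"{sid:<8s}{year:4d}{fields}")
            i += len(chunk)
            year += n
    Path(path).write_text("\n".join(lines) + "\n")
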