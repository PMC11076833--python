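"""Read-to-row layout by greedy interval scheduling, plus dense-region subsampling.

Reads are placed like IGV stacks them: sort display spans by start, then put
each span in the lowest-index row whose rightmost occupant (plus an inter-read
gap) ends at or before the span's start.  With gap 0 this first-fit rule is
optimal for interval graphs — the number of rows equals the maximum overlap
depth.  When a region is over-covered, reads are subsampled to a row cap with
priority given to SV-supporting reads so evidence is never hidden before
reference reads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .breakpoints import ReadStructure

DEFAULT_ROW_GAP = 5
DEFAULT_MAX_ROWS = 200


@dataclass
class LayoutAssignment:
    rows: list[list[str]] = field(default_factory=list)
    read_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    max_rows: int = DEFAULT_MAX_ROWS

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row_of(self, read_name: str) -> int:
        for i, row in enumerate(self.rows):
            if read_name in row:
                return i
        raise KeyError(read_name)


def assign_rows(
    spans: list[tuple[str, int, int]],
    gap: int = DEFAULT_ROW_GAP,
    max_rows: int = DEFAULT_MAX_ROWS,
) -> LayoutAssignment:
    """First-fit interval scheduling of display spans into rows.

    ``spans`` are (read_name, start, end) with end > start; ``gap`` is the
    minimum reference-space separation between reads sharing a row.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    for name, s, e in spans:
        if e <= s:
            raise ValueError(f"span for {name!r} has end <= start")
    ordered = sorted(spans, key=lambda t: (t[1], t[2], t[0]))
    rows: list[list[str]] = []
    row_ends: list[int] = []
    span_map: dict[str, tuple[int, int]] = {}
    for name, s, e in ordered:
        span_map[name] = (s, e)
        placed = False
        for i, last_end in enumerate(row_ends):
            if last_end + gap <= s:
                rows[i].append(name)
                row_ends[i] = e
                placed = True
                break
        if not placed:
            rows.append([name])
            row_ends.append(e)
    return LayoutAssignment(rows=rows, read_span=span_map, max_rows=max_rows)


def _stable_seed(seed: int, key: str = "") -> int:
    """Derive a reproducible 31-bit seed from a base seed and a record key."""
    h = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def subsample_reads(
    structures: list[ReadStructure],
    max_rows: int = DEFAULT_MAX_ROWS,
    seed: int = 0,
    key: str = "",
) -> list[str]:
    """Deterministically pick at most ``max_rows`` reads for display.

    SV-supporting reads (any non-REF structure) are retained first; remaining
    capacity is filled with reference reads sampled without replacement using
    a seed derived from ``seed`` and the per-record ``key``.
    """
    if max_rows <= 0:
        raise ValueError("max_rows must be > 0")
    if len(structures) <= max_rows:
        return [st.read_name for st in structures]
    rng = np.random.default_rng(_stable_seed(seed, key))
    supporting = [st.read_name for st in structures if st.sv_type != "REF"]
    reference = [st.read_name for st in structures if st.sv_type == "REF"]
    if len(supporting) >= max_rows:
        idx = rng.choice(len(supporting), size=max_rows, replace=False)
        return [supporting[i] for i in sorted(idx)]
    n_ref = max_rows - len(supporting)
    idx = rng.choice(len(reference), size=n_ref, replace=False)
    return supporting + [reference[i] for i in sorted(idx)]
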