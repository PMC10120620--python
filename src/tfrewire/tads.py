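"""Topologically-associated-domain (TAD) maps.

TAD and loop calls arrive from upstream Hi-C processing as 3-column domain
tables or BEDPE; this module only stores and queries them. Callers sometimes
emit nested or overlapping domains; lookups therefore resolve a position to
the SMALLEST domain containing it, which scopes enhancer-gene assignment
conservatively.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .intervals import BedParseError, GenomicInterval, IntervalSet

__all__ = ["TadMap", "read_tads", "write_tads"]


class TadMap:
    """Per-chromosome TAD intervals with smallest-containing-domain lookup."""

    def __init__(self, tads: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, np.ndarray] = {}
        rows: dict[str, list[tuple[int, int, int]]] = {}
        tad_list = sorted(tads, key=lambda t: (t.chrom, t.start, t.end))
        for i, t in enumerate(tad_list):
            rows.setdefault(t.chrom, []).append((t.start, t.end, i))
        self._tads = tad_list
        for chrom, r in rows.items():
            self._by_chrom[chrom] = np.asarray(r, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._tads)

    def __iter__(self):
        return iter(self._tads)

    @property
    def tads(self) -> list[GenomicInterval]:
        return list(self._tads)

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet(self._tads, label="tads")

    def is_nonoverlapping(self) -> bool:
        for arr in self._by_chrom.values():
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                return False
        return True

    def tad_index_of(self, chrom: str, pos: int) -> Optional[int]:
        """Index (into self.tads) of the smallest TAD containing ``pos``,
        or None when no domain contains it."""
        arr = self._by_chrom.get(chrom)
        if arr is None:
            return None
        hits = (arr[:, 0] <= pos) & (pos < arr[:, 1])
        if not hits.any():
            return None
        cand = arr[hits]
        widths = cand[:, 1] - cand[:, 0]
        best = cand[np.argmin(widths)]
        return int(best[2])

    def containing(self, chrom: str, pos: int) -> Optional[GenomicInterval]:
        idx = self.tad_index_of(chrom, pos)
        return None if idx is None else self._tads[idx]


def read_tads(path: str | Path) -> TadMap:
    """Read a TAD table: 3-column TSV (chrom, start, end) or BEDPE-style
    6-column rows whose two anchors delimit the domain on one chromosome."""
    path = Path(path)
    tads: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 6 and fields[0] == fields[3]:
                    start = min(int(fields[1]), int(fields[4]))
                    end = max(int(fields[2]), int(fields[5]))
                    tads.append(GenomicInterval(fields[0], start, end))
                elif len(fields) >= 3:
                    tads.append(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                    )
                else:
                    raise ValueError("expected >= 3 fields")
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return TadMap(tads)


def write_tads(tads: TadMap, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
    return path
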