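"""Coordinate-convention-safe genomic interval algebra and BED-family I/O.

All coordinates are 0-based half-open (BED native): an interval covers
``[start, end)``, its length is ``end - start``, and two intervals that merely
abut (``end_a == start_b``) never overlap. Every other module in the package
consumes :class:`IntervalSet`, so keeping a single convention here prevents
off-by-one drift between formats.

Chromosome names are matched by exact string comparison; no "chr" prefix
normalization is attempted unless the caller supplies an alias table to
:func:`read_bed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "read_bedgraph",
    "write_bedgraph",
]


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph/BEDPE records; carries the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        lengths = dict(self.chrom_lengths)
        for name in names:
            if name not in lengths:
                raise ValueError(f"no length supplied for chromosome {name!r}")
            if int(lengths[name]) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom])

    def check_interval(self, iv: "GenomicInterval") -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.length_of(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length_of(iv.chrom)}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional signal and name.

    ``signal`` is a nonnegative real (peak score / area under the signal
    curve); ``name`` is a free-text label such as a peak id.
    """

    chrom: str
    start: int
    end: int
    signal: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.signal is not None and self.signal < 0:
            raise ValueError("signal must be nonnegative")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)`` with chromosomes in
    first-appearance order (or layout order when a layout is given at read
    time). Duplicates and overlaps are permitted until :meth:`merge` is
    called; after a merge the set is pairwise non-overlapping per chromosome.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
    ) -> None:
        ivs = list(intervals)
        ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._intervals: list[GenomicInterval] = ivs
        self.label = label
        self._by_chrom: Optional[dict[str, np.ndarray]] = None

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<IntervalSet{lab}: {len(self)} intervals>"

    @property
    def intervals(self) -> Sequence[GenomicInterval]:
        return tuple(self._intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def total_bp(self) -> int:
        """Total covered bases counting overlaps multiply (use merge first
        for a footprint)."""
        return sum(len(iv) for iv in self._intervals)

    # -- indexed arrays -----------------------------------------------------

    def _arrays(self) -> dict[str, np.ndarray]:
        """Per-chromosome (idx, start, end) arrays, start-sorted, cached."""
        if self._by_chrom is None:
            by: dict[str, list[list[int]]] = {}
            for i, iv in enumerate(self._intervals):
                by.setdefault(iv.chrom, []).append([i, iv.start, iv.end])
            self._by_chrom = {
                chrom: np.asarray(rows, dtype=np.int64)
                for chrom, rows in by.items()
            }
        return self._by_chrom

    # -- core algebra -------------------------------------------------------

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Fuse intervals separated by at most ``gap`` bases.

        The fused interval's signal is the sum of its members' signals (None
        signals propagate as None when every member lacks one); its name is
        dropped. With ``gap=0`` abutting intervals ARE fused (distance 0);
        overlap is not required.
        """
        if gap < 0:
            raise ValueError("gap must be >= 0")
        out: list[GenomicInterval] = []
        cur: Optional[list] = None  # [chrom, start, end, signal_sum, any_signal]
        for iv in self._intervals:
            if cur is not None and iv.chrom == cur[0] and iv.start - cur[2] <= gap:
                cur[2] = max(cur[2], iv.end)
                if iv.signal is not None:
                    cur[3] += iv.signal
                    cur[4] = True
            else:
                if cur is not None:
                    out.append(
                        GenomicInterval(
                            cur[0], cur[1], cur[2], cur[3] if cur[4] else None
                        )
                    )
                cur = [iv.chrom, iv.start, iv.end,
                       iv.signal if iv.signal is not None else 0.0,
                       iv.signal is not None]
        if cur is not None:
            out.append(
                GenomicInterval(cur[0], cur[1], cur[2], cur[3] if cur[4] else None)
            )
        return IntervalSet(out, label=self.label)

    def overlap_pairs(
        self, other: "IntervalSet", min_bp: int = 1
    ) -> list[tuple[GenomicInterval, GenomicInterval]]:
        """All pairs (a, b), a in self, b in other, sharing >= min_bp bases."""
        if min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        pairs_idx = self.overlap_pair_indices(other, min_bp=min_bp)
        return [(self._intervals[i], other._intervals[j]) for i, j in pairs_idx]

    def overlap_pair_indices(
        self, other: "IntervalSet", min_bp: int = 1
    ) -> list[tuple[int, int]]:
        """Index pairs into (self, other) for overlaps of >= min_bp bases."""
        if min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        out: list[tuple[int, int]] = []
        mine = self._arrays()
        theirs = other._arrays()
        for chrom, a in mine.items():
            b = theirs.get(chrom)
            if b is None:
                continue
            b_starts = b[:, 1]
            # running max of ends lets us prune candidates entirely left of a
            b_end_cummax = np.maximum.accumulate(b[:, 2])
            for idx_a, s_a, e_a in a:
                hi = int(np.searchsorted(b_starts, e_a - min_bp, side="right"))
                if hi == 0:
                    continue
                lo = int(np.searchsorted(b_end_cummax[:hi], s_a + min_bp,
                                         side="left"))
                if lo >= hi:
                    continue
                cand = b[lo:hi]
                ov = (np.minimum(cand[:, 2], e_a)
                      - np.maximum(cand[:, 1], s_a))
                for row in cand[ov >= min_bp]:
                    out.append((int(idx_a), int(row[0])))
        out.sort()
        return out

    def overlaps_any(self, other: "IntervalSet", min_bp: int = 1) -> np.ndarray:
        """Boolean flag per interval of self: shares >= min_bp bases with
        any interval of ``other``."""
        flags = np.zeros(len(self), dtype=bool)
        for i, _ in self.overlap_pair_indices(other, min_bp=min_bp):
            flags[i] = True
        return flags

    def count_distinct_overlappers(
        self, others: Mapping[str, "IntervalSet"], min_bp: int = 1
    ) -> np.ndarray:
        """Per interval of self, the number of sets in ``others`` with at
        least one overlapping interval."""
        counts = np.zeros(len(self), dtype=np.int64)
        for other in others.values():
            counts += self.overlaps_any(other, min_bp=min_bp).astype(np.int64)
        return counts

    def with_label(self, label: str) -> "IntervalSet":
        out = IntervalSet.__new__(IntervalSet)
        out._intervals = self._intervals
        out.label = label
        out._by_chrom = self._by_chrom
        return out


# ---------------------------------------------------------------------------
# BED-family readers/writers
# ---------------------------------------------------------------------------

def _format_signal(x: float) -> str:
    """Stable, round-trippable text form for a signal value."""
    return repr(float(x))


def read_bed(
    path: str | Path,
    signal_column: Optional[int] = None,
    layout: Optional[GenomeLayout] = None,
    label: str = "",
    aliases: Optional[Mapping[str, str]] = None,
) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    Parameters
    ----------
    signal_column:
        1-based column index to take the per-interval signal from (e.g. 5 for
        the BED5 score column). When None, intervals carry no signal.
    layout:
        When given, every record is validated against it; unknown chromosomes
        or out-of-bounds coordinates are rejected.
    aliases:
        Optional chromosome-name alias table applied before matching
        (e.g. ``{"1": "chr1"}``); matching is otherwise exact.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            chrom = fields[0]
            if aliases:
                chrom = aliases.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            signal = None
            if signal_column is not None:
                if len(fields) < signal_column:
                    raise BedParseError(
                        f"{path}:{lineno}: no column {signal_column}"
                    )
                try:
                    signal = float(fields[signal_column - 1])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric signal"
                    ) from exc
            iv = GenomicInterval(chrom, start, end, signal=signal, name=name)
            if layout is not None:
                layout.check_interval(iv)
            intervals.append(iv)
    return IntervalSet(intervals, label=label or path.stem)


def write_bed(a: IntervalSet, path: str | Path) -> Path:
    """Write an IntervalSet as BED3/4/5.

    Sets with signal are written as BED5 (name '.', score in column 5) so that
    ``read_bed(..., signal_column=5)`` round-trips exactly; named intervals
    keep their name in column 4.
    """
    path = Path(path)
    has_signal = any(iv.signal is not None for iv in a)
    with path.open("w") as fh:
        for iv in a:
            if has_signal:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_format_signal(iv.signal if iv.signal is not None else 0.0)}\n"
                )
            elif iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return path


def read_bedpe(
    path: str | Path, layout: Optional[GenomeLayout] = None
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read a BEDPE file (6 coordinate columns) as a list of anchor pairs."""
    path = Path(path)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 6 fields for BEDPE"
                )
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if layout is not None:
                layout.check_interval(a)
                layout.check_interval(b)
            pairs.append((a, b))
    return pairs


def write_bedpe(
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for a, b in pairs:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )
    return path


@dataclass
class SignalTrack:
    """A bedGraph-style step function per chromosome.

    ``segments[chrom]`` holds parallel arrays (starts, ends, values) sorted by
    start and non-overlapping; the track is 0 outside listed segments.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean track value over [start, end); regions off the track are 0."""
        if end <= start:
            raise ValueError("empty window")
        seg = self.segments.get(chrom)
        if seg is None:
            return 0.0
        starts, ends, values = seg
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]) / (end - start))


def read_bedgraph(path: str | Path) -> SignalTrack:
    path = Path(path)
    by: dict[str, list[tuple[int, int, float]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path}:{lineno}: expected 4 fields for bedGraph"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed record") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: empty segment")
            by.setdefault(fields[0], []).append((start, end, value))
    segments = {}
    for chrom, rows in by.items():
        rows.sort()
        arr = np.asarray(rows, dtype=float)
        segments[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(segments)


def write_bedgraph(track: SignalTrack, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{_format_signal(v)}\n")
    return path
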