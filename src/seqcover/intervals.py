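"""Genomic intervals, regions of interest, and window tiling.

All coordinates are 0-based half-open (BED convention) internally; readers
for 1-based formats (GFF) convert at the boundary.  A :class:`RegionSet`
holds the region of interest (ROI) over which datasets are built, and
:func:`tile` turns it into the :class:`BinGrid` of fixed-size model windows
that indexes every downstream tensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class RegionParseError(ValueError):
    """Raised when a region file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, and
    ``strand`` one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp).  Unknown-chromosome lookups raise."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = dict(sizes)

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        """Read a UCSC two-column ``chrom.sizes`` text file."""
        sizes = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise RegionParseError(f"{path}:{lineno}: expected 2 columns")
                try:
                    sizes[parts[0]] = int(parts[1])
                except ValueError as exc:
                    raise RegionParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        return cls(sizes)

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes


@dataclass
class RegionSet:
    """An ordered, strand-aware set of intervals bound to chromosome sizes.

    Intervals are normalized to sorted ``(chrom, start, end)`` order on
    construction and every chromosome must be present in ``sizes``.
    """

    intervals: list[GenomicInterval]
    sizes: ChromSizes

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.end > self.sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {self.sizes[iv.chrom]}"
                )
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def to_bed(self, path) -> None:
        """Write as BED6 (name ``.``, score 0 where absent)."""
        with open(path, "w") as fh:
            for iv in self.intervals:
                score = 0 if iv.score is None else iv.score
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")


@dataclass
class BinGrid:
    """Tiling of a :class:`RegionSet` into fixed-size model windows.

    Every window has length ``binsize``; ``flank`` is recorded here and
    applied at data-fetch time, so the *effective* fetch range of window
    ``w`` is ``[w.start - flank, w.end + flank)``.
    """

    windows: list[GenomicInterval]
    binsize: int
    stepsize: int
    flank: int
    sizes: ChromSizes
    source: RegionSet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for w in self.windows:
            if len(w) != self.binsize:
                raise ValueError(f"window {w} does not have length binsize={self.binsize}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.windows[i]

    @property
    def window_length(self) -> int:
        """Effective fetch length: binsize + 2 * flank."""
        return self.binsize + 2 * self.flank

    def fetch_range(self, i: int) -> tuple[str, int, int]:
        """Flanked (chrom, start, end) of window ``i``; may exceed bounds."""
        w = self.windows[i]
        return w.chrom, w.start - self.flank, w.end + self.flank

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.chrom, None)
        return list(seen)


# ---------------------------------------------------------------------------
# readers


def _parse_bed_line(parts: Sequence[str], n_min: int, lineno: int, path) -> tuple:
    if len(parts) < n_min:
        raise RegionParseError(
            f"{path}:{lineno}: expected >= {n_min} columns, got {len(parts)}"
        )
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise RegionParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    return parts[0], start, end


def read_regions(path, format: str, sizes: ChromSizes) -> RegionSet:
    """Parse a region file into a :class:`RegionSet`.

    ``format`` is one of ``bed3``, ``bed6``, ``narrowpeak`` or ``gff``.
    BED-family coordinates are taken verbatim (0-based half-open); GFF is
    converted from 1-based inclusive to half-open (``start-1``, ``end``).
    Records on chromosomes absent from ``sizes`` raise a ``KeyError``
    naming the chromosome.
    """
    fmt = format.lower()
    if fmt not in {"bed3", "bed6", "narrowpeak", "gff"}:
        raise ValueError(f"unknown region format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if fmt == "gff":
                if len(parts) < 8:
                    raise RegionParseError(f"{path}:{lineno}: expected >= 8 GFF columns")
                chrom = parts[0]
                try:
                    start, end = int(parts[3]) - 1, int(parts[4])
                except ValueError as exc:
                    raise RegionParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                strand = parts[6] if parts[6] in ("+", "-") else "."
                score = None
                if parts[5] not in (".", ""):
                    score = float(parts[5])
            elif fmt == "bed3":
                chrom, start, end = _parse_bed_line(parts, 3, lineno, path)
                strand, score = ".", None
            elif fmt == "bed6":
                chrom, start, end = _parse_bed_line(parts, 3, lineno, path)
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
                strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            else:  # narrowpeak: 10-column BED6+4; column 5 is the score
                chrom, start, end = _parse_bed_line(parts, 10, lineno, path)
                score = float(parts[4]) if parts[4] != "." else None
                strand = parts[5] if parts[5] in ("+", "-") else "."
            # raises KeyError naming the chromosome if absent
            sizes[chrom]
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, score))
            except ValueError as exc:
                raise RegionParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(intervals, sizes)


# ---------------------------------------------------------------------------
# set operations


def extend_and_merge(r: RegionSet, ext: int) -> RegionSet:
    """Extend every interval by ``ext`` bp on both sides, clip to chromosome
    bounds, and merge overlapping or bookended intervals.

    This is the ROI construction rule "union of peaks extended by E":
    strand and score are dropped on merge (merged intervals are unstranded).
    """
    if ext < 0:
        raise ValueError("ext must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in r:
        start = max(0, iv.start - ext)
        end = min(r.sizes[iv.chrom], iv.end + ext)
        by_chrom.setdefault(iv.chrom, []).append((start, end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return RegionSet(merged, r.sizes)


def subtract(r: RegionSet, mask: RegionSet) -> RegionSet:
    """Remove every base covered by ``mask`` from ``r``.

    Intervals are split where the mask bisects them; empty remainders are
    dropped.  The typical use is blacklist removal from an ROI.
    """
    if r.sizes != mask.sizes:
        raise ValueError("RegionSets must share ChromSizes")
    mask_merged = extend_and_merge(mask, 0) if len(mask) else mask
    mask_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in mask_merged:
        mask_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in r:
        pieces = [(iv.start, iv.end)]
        for m in mask_by_chrom.get(iv.chrom, []):
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if m.end <= s or m.start >= e:
                    nxt.append((s, e))
                    continue
                if m.start > s:
                    nxt.append((s, m.start))
                if m.end < e:
                    nxt.append((m.end, e))
            pieces = nxt
        for s, e in pieces:
            out.append(replace(iv, start=s, end=e))
    return RegionSet(out, r.sizes)


def tile(r: RegionSet, binsize: int, stepsize: int, flank: int = 0) -> BinGrid:
    """Tile each ROI interval into windows of ``binsize`` advancing by
    ``stepsize``, anchored at the interval start.

    Windows are emitted while ``start + binsize <= interval.end``;
    intervals shorter than ``binsize`` yield no windows (logged).
    ``flank`` is recorded on the grid, not applied to window coordinates.
    """
    if binsize <= 0 or stepsize <= 0:
        raise ValueError("binsize and stepsize must be positive")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows: list[GenomicInterval] = []
    for iv in r:
        if len(iv) < binsize:
            logger.info(
                "interval %s:%d-%d shorter than binsize %d: no windows",
                iv.chrom, iv.start, iv.end, binsize,
            )
            continue
        for s in range(iv.start, iv.end - binsize + 1, stepsize):
            windows.append(GenomicInterval(iv.chrom, s, s + binsize, iv.strand))
    return BinGrid(windows, binsize, stepsize, flank, r.sizes, source=r)


def label_by_overlap(grid: BinGrid, peaks: RegionSet) -> np.ndarray:
    """Binary label per window: 1 iff the window (without flank) shares at
    least one base with any peak."""
    if grid.sizes != peaks.sizes:
        raise ValueError("grid and peaks must share ChromSizes")
    merged = extend_and_merge(peaks, 0) if len(peaks) else peaks
    spans: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_by_chrom = {c: np.array([s for s, _ in v], dtype=np.int64) for c, v in spans.items()}
    ends_by_chrom = {c: np.array([e for _, e in v], dtype=np.int64) for c, v in spans.items()}
    labels = np.zeros(len(grid), dtype=np.int8)
    for i, w in enumerate(grid):
        starts = starts_by_chrom.get(w.chrom)
        if starts is None or starts.size == 0:
            continue
        ends = ends_by_chrom[w.chrom]
        # merged intervals are disjoint & sorted: the only candidate is the
        # last one starting before w.end
        j = int(np.searchsorted(starts, w.end)) - 1
        if j >= 0 and ends[j] > w.start:
            labels[i] = 1
    return labels


def split_by_chromosome(
    grid: BinGrid, holdout: Mapping[str, Iterable[str]], default: str = "train"
) -> dict[str, np.ndarray]:
    """Partition window indices by chromosome.

    ``holdout`` maps partition name -> chromosome names (e.g.
    ``{"val": {"chr2"}, "test": {"chr3"}}``); every window on a chromosome
    not named in any partition goes to ``default``.
    """
    chrom_to_part: dict[str, str] = {}
    for part, chroms in holdout.items():
        for c in chroms:
            if c in chrom_to_part:
                raise ValueError(f"chromosome {c!r} assigned to both "
                                 f"{chrom_to_part[c]!r} and {part!r}")
            chrom_to_part[c] = part
    parts: dict[str, list[int]] = {default: []}
    for part in holdout:
        parts.setdefault(part, [])
    for i, w in enumerate(grid):
        parts.setdefault(chrom_to_part.get(w.chrom, default), []).append(i)
    grid_chroms = set(grid.chroms())
    for part, chroms in holdout.items():
        missing = set(chroms) - grid_chroms
        if missing:
            logger.warning("partition %r: chromosomes %s absent from grid", part, sorted(missing))
    return {name: np.array(idx, dtype=np.int64) for name, idx in parts.items()}
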