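"""Binned coverage tensors from alignments, tracks and interval files.

A :class:`CoverageDataset` holds a ``(windows, bins, strands, conditions)``
tensor over a :class:`~seqcover.intervals.BinGrid`: each window's flanked
fetch range is divided into bins of ``resolution`` bp.  Constructors ingest

* SAM/BAM alignments — each retained read contributes a count of 1 at the
  bin containing its 5' end (leftmost aligned base on '+', rightmost on '-'),
  the standard convention for cleavage assays such as DNase-seq;
* bigWig / bedGraph tracks — per-base values aggregated per bin (sum or
  mean), missing data treated as 0;
* BED-like interval files — binary overlap, max score, or record count
  per bin.

Bins that fall outside chromosome bounds are zero-padded so every window
yields a fixed-shape tensor.  One condition per input file, named after the
file basename.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .intervals import BinGrid, RegionSet, read_regions

logger = logging.getLogger(__name__)


@dataclass
class CoverageDataset:
    """Per-window binned signal with axes (window, bin, strand, condition)."""

    backend: object
    resolution: int
    grid: BinGrid = field(repr=False)
    conditions: list[str]
    stranded: bool

    def __post_init__(self) -> None:
        L = self.grid.window_length
        if L % self.resolution != 0:
            raise ValueError(
                f"window length {L} (binsize + 2*flank) not divisible by "
                f"resolution {self.resolution}"
            )
        expect = (
            len(self.grid),
            self.bins_per_window,
            2 if self.stranded else 1,
            len(self.conditions),
        )
        if tuple(self.backend.shape) != expect:
            raise ValueError(f"tensor shape {self.backend.shape} != expected {expect}")

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        grid: BinGrid,
        resolution: int,
        conditions: Sequence[str] | None = None,
        stranded: bool = False,
        storage: str = "ndarray",
        storage_path=None,
    ) -> "CoverageDataset":
        from .storage import make_backend

        values = np.asarray(values, dtype=np.float64)
        if values.ndim == 2:
            values = values[:, :, None, None]
        elif values.ndim == 3:
            values = values[:, :, None, :]
        if conditions is None:
            conditions = [f"c{i}" for i in range(values.shape[-1])]
        backend = make_backend(values, storage, storage_path)
        return cls(backend, resolution, grid, list(conditions), stranded)

    @property
    def bins_per_window(self) -> int:
        return self.grid.window_length // self.resolution

    @property
    def strand_dim(self) -> int:
        return 2 if self.stranded else 1

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.backend.shape)

    @property
    def values(self) -> np.ndarray:
        """Materialized dense tensor (windows, bins, strands, conditions)."""
        return self.backend.materialize()

    def __len__(self) -> int:
        return self.shape[0]

    def __getitem__(self, i):
        return self.values[i]

    def with_values(self, values: np.ndarray) -> "CoverageDataset":
        """Same genomic anchoring, new dense tensor."""
        from .storage import DenseBackend

        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} != {self.shape}")
        return replace(self, backend=DenseBackend(values))


def _condition_name(path) -> str:
    name = Path(path).name
    for suffix in (".bam", ".sam", ".bw", ".bigwig", ".bigWig", ".bedgraph",
                   ".bedGraph", ".bg", ".bed", ".narrowPeak", ".narrowpeak", ".gz"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def _as_list(paths) -> list:
    if isinstance(paths, (str, Path)):
        return [paths]
    return list(paths)


# ---------------------------------------------------------------------------
# BAM / SAM


def _read_five_prime_ends(path, min_mapq: int):
    """Stream (chrom -> (sorted 5'-end positions, strand flags)) from SAM/BAM.

    The 5' end is reference_start for forward reads and reference_end - 1
    for reverse reads.  Unmapped and sub-min_mapq reads are skipped; mates
    of a pair count independently.
    """
    pos_by_chrom: dict[str, list[int]] = {}
    strand_by_chrom: dict[str, list[int]] = {}
    n_kept = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as aln:
        for read in aln.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            pos_by_chrom.setdefault(chrom, []).append(pos)
            strand_by_chrom.setdefault(chrom, []).append(1 if read.is_reverse else 0)
            n_kept += 1
    out = {}
    for chrom, positions in pos_by_chrom.items():
        p = np.array(positions, dtype=np.int64)
        s = np.array(strand_by_chrom[chrom], dtype=np.int64)
        order = np.argsort(p, kind="stable")
        out[chrom] = (p[order], s[order])
    return out, n_kept


def coverage_from_bam(
    aln,
    grid: BinGrid,
    resolution: int,
    stranded: bool = False,
    min_mapq: int = 0,
    storage: str = "ndarray",
    storage_path=None,
) -> CoverageDataset:
    """Count read 5' ends per bin from one or more SAM/BAM files.

    With ``stranded=True`` forward/reverse reads go to separate strand
    channels; otherwise they are summed into one.  One condition per file.
    """
    paths = _as_list(aln)
    n_bins = grid.window_length // resolution
    if grid.window_length % resolution != 0:
        raise ValueError(
            f"resolution {resolution} does not divide window length {grid.window_length}"
        )
    sdim = 2 if stranded else 1
    tensor = np.zeros((len(grid), n_bins, sdim, len(paths)), dtype=np.float64)
    for ci, path in enumerate(paths):
        ends, n_kept = _read_five_prime_ends(path, min_mapq)
        logger.info("%s: %d reads retained", path, n_kept)
        for wi in range(len(grid)):
            chrom, fs, fe = grid.fetch_range(wi)
            if chrom not in ends:
                continue
            pos, strands = ends[chrom]
            lo = np.searchsorted(pos, fs, side="left")
            hi = np.searchsorted(pos, fe, side="left")
            if hi == lo:
                continue
            bins = (pos[lo:hi] - fs) // resolution
            if stranded:
                for sidx in (0, 1):
                    sel = bins[strands[lo:hi] == sidx]
                    np.add.at(tensor[wi, :, sidx, ci], sel, 1.0)
            else:
                np.add.at(tensor[wi, :, 0, ci], bins, 1.0)
    from .storage import make_backend

    backend = make_backend(tensor, storage, storage_path)
    return CoverageDataset(backend, resolution, grid, [_condition_name(p) for p in paths], stranded)


# ---------------------------------------------------------------------------
# bigWig / bedGraph


class _BedGraphTrack:
    """Per-base lookup over a bedGraph text file (gaps read as 0)."""

    def __init__(self, path):
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        vals: dict[str, list[float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                starts.setdefault(c, []).append(s)
                ends.setdefault(c, []).append(e)
                vals.setdefault(c, []).append(v)
        self._tracks = {}
        for c in starts:
            order = np.argsort(np.array(starts[c]))
            self._tracks[c] = (
                np.array(starts[c])[order],
                np.array(ends[c])[order],
                np.array(vals[c])[order],
            )

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._tracks:
            return out
        starts, ends, vals = self._tracks[chrom]
        for s, e, v in zip(starts, ends, vals):
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                out[lo - start : hi - start] = v
        return out


def _per_base_values(path, chrom: str, start: int, end: int, sizes) -> np.ndarray:
    """Per-base track values over [start, end), zero-padded out of bounds."""
    out = np.zeros(end - start, dtype=np.float64)
    chrom_len = sizes[chrom]  # raises KeyError for unknown chromosome
    lo, hi = max(0, start), min(chrom_len, end)
    if hi <= lo:
        return out
    if isinstance(path, _BedGraphTrack):
        out[lo - start : hi - start] = path.values(chrom, lo, hi)
        return out
    import pyBigWig

    with pyBigWig.open(str(path)) as bw:
        if chrom not in bw.chroms():
            return out
        hi2 = min(hi, bw.chroms()[chrom])
        if hi2 > lo:
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, lo, hi2, numpy=True), dtype=np.float64)
            )
            out[lo - start : hi2 - start] = vals
    return out


def _is_bedgraph(path) -> bool:
    return str(path).endswith((".bedgraph", ".bedGraph", ".bg"))


def coverage_from_bigwig(
    track,
    grid: BinGrid,
    resolution: int,
    agg: str = "sum",
    storage: str = "ndarray",
    storage_path=None,
) -> CoverageDataset:
    """Aggregate per-base track values per bin, by sum (default) or mean.

    Accepts bigWig files and bedGraph text (by extension).  Missing or NaN
    bases read as 0; chromosomes in the grid but absent from the chromosome
    sizes raise.
    """
    if agg not in ("sum", "mean"):
        raise ValueError(f"agg must be 'sum' or 'mean', got {agg!r}")
    paths = _as_list(track)
    n_bins = grid.window_length // resolution
    if grid.window_length % resolution != 0:
        raise ValueError(
            f"resolution {resolution} does not divide window length {grid.window_length}"
        )
    tensor = np.zeros((len(grid), n_bins, 1, len(paths)), dtype=np.float64)
    for ci, path in enumerate(paths):
        src = _BedGraphTrack(path) if _is_bedgraph(path) else path
        for wi in range(len(grid)):
            chrom, fs, fe = grid.fetch_range(wi)
            base = _per_base_values(src, chrom, fs, fe, grid.sizes)
            binned = base.reshape(n_bins, resolution)
            tensor[wi, :, 0, ci] = binned.sum(axis=1) if agg == "sum" else binned.mean(axis=1)
    from .storage import make_backend

    backend = make_backend(tensor, storage, storage_path)
    return CoverageDataset(
        backend, resolution, grid, [_condition_name(p) for p in paths], stranded=False
    )


# ---------------------------------------------------------------------------
# BED-like


def coverage_from_bed(
    bed,
    grid: BinGrid,
    resolution: int,
    mode: str = "binary",
    format: str | None = None,
    storage: str = "ndarray",
    storage_path=None,
) -> CoverageDataset:
    """Rasterize interval records onto the grid's bins.

    ``mode='binary'``: 1 iff any record overlaps the bin; ``'score'``: max
    record score over the bin (0 if none; requires a score column, so BED3
    input is rejected); ``'count'``: number of overlapping records.
    Format is sniffed from the extension/column count unless given.
    """
    if mode not in ("binary", "score", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    paths = _as_list(bed)
    n_bins = grid.window_length // resolution
    if grid.window_length % resolution != 0:
        raise ValueError(
            f"resolution {resolution} does not divide window length {grid.window_length}"
        )
    tensor = np.zeros((len(grid), n_bins, 1, len(paths)), dtype=np.float64)
    for ci, path in enumerate(paths):
        fmt = format or _sniff_bed_format(path)
        if mode == "score" and fmt == "bed3":
            raise ValueError(f"{path}: score mode requires a score column (BED3 has none)")
        regions = read_regions(path, fmt, grid.sizes)
        by_chrom: dict[str, list] = {}
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        arrays = {
            c: (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
                np.array(
                    [iv.score if iv.score is not None else 0.0 for iv in ivs],
                    dtype=np.float64,
                ),
            )
            for c, ivs in by_chrom.items()
        }
        for wi in range(len(grid)):
            chrom, fs, _fe = grid.fetch_range(wi)
            if chrom not in arrays:
                continue
            starts, ends, scores = arrays[chrom]
            for b in range(n_bins):
                bs, be = fs + b * resolution, fs + (b + 1) * resolution
                hit = (starts < be) & (ends > bs)
                if not hit.any():
                    continue
                if mode == "binary":
                    tensor[wi, b, 0, ci] = 1.0
                elif mode == "count":
                    tensor[wi, b, 0, ci] = float(hit.sum())
                else:
                    tensor[wi, b, 0, ci] = float(scores[hit].max())
    from .storage import make_backend

    backend = make_backend(tensor, storage, storage_path)
    return CoverageDataset(
        backend, resolution, grid, [_condition_name(p) for p in paths], stranded=False
    )


def _sniff_bed_format(path) -> str:
    name = str(path).lower()
    if name.endswith((".narrowpeak",)):
        return "narrowpeak"
    if name.endswith((".gff", ".gff3", ".gtf")):
        return "gff"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            n = len(line.split("\t")) if "\t" in line else len(line.split())
            if n >= 10:
                return "narrowpeak"
            if n >= 5:
                return "bed6"
            return "bed3"
    return "bed3"


# ---------------------------------------------------------------------------


def aggregate_windows(c: CoverageDataset, op: str = "sum") -> np.ndarray:
    """Reduce the bin axis to one scalar per (window, condition).

    The strand axis is summed first; ``op`` is one of sum/mean/max.  This is
    the promoter-signal summation used for e.g. CAGE-tag regression.
    """
    if op not in ("sum", "mean", "max"):
        raise ValueError(f"unknown op {op!r}")
    v = c.values.sum(axis=2)  # (windows, bins, conditions)
    if op == "sum":
        return v.sum(axis=1)
    if op == "mean":
        return v.mean(axis=1)
    return v.max(axis=1)
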