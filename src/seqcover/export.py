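"""Export prediction arrays back to genome-browser formats.

A model's per-window predictions are re-anchored to the genome by wrapping
them in a :class:`~seqcover.coverage.CoverageDataset` over the grid they
were computed on, then written as bigWig/bedGraph tracks (one file per
condition) or BED6 records (one per bin).  Where stepped windows overlap,
the exported per-base value is the mean over all bins covering that base;
bases covered by no window are absent from the track.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import CoverageDataset
from .intervals import BinGrid, GenomicInterval


def dataset_from_array(
    values: np.ndarray,
    grid: BinGrid,
    resolution: int,
    conditions: Sequence[str] | None = None,
) -> CoverageDataset:
    """Anchor a ``(windows, bins[, conditions])`` or per-window ``(windows,)``
    prediction array to a grid.

    With ``resolution == window_length`` a 1-D array of per-window scalars
    becomes a one-bin-per-window dataset.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != len(grid):
        raise ValueError(
            f"leading dimension {values.shape[0]} != grid window count {len(grid)}"
        )
    expect_bins = grid.window_length // resolution
    if grid.window_length % resolution != 0 or values.shape[1] != expect_bins:
        raise ValueError(
            f"got {values.shape[1]} bins but resolution {resolution} over a "
            f"{grid.window_length}-bp window implies {expect_bins}"
        )
    return CoverageDataset.from_values(values, grid, resolution, conditions)


def _per_base_accumulate(c: CoverageDataset, condition: int):
    """Per-chromosome (sum, count) accumulators over flanked bin spans."""
    v = c.values.sum(axis=2)[:, :, condition]  # (windows, bins)
    res = c.resolution
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for wi in range(len(c.grid)):
        chrom, fs, fe = c.grid.fetch_range(wi)
        if chrom not in sums:
            n = c.grid.sizes[chrom]
            sums[chrom] = np.zeros(n, dtype=np.float64)
            counts[chrom] = np.zeros(n, dtype=np.int64)
        for b in range(c.bins_per_window):
            bs, be = fs + b * res, fs + (b + 1) * res
            lo, hi = max(0, bs), min(c.grid.sizes[chrom], be)
            if hi > lo:
                sums[chrom][lo:hi] += v[wi, b]
                counts[chrom][lo:hi] += 1
    return sums, counts


def _runs(values: np.ndarray, covered: np.ndarray):
    """Yield (start, end, value) runs over covered bases."""
    n = len(values)
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i + 1
        while j < n and covered[j] and values[j] == values[i]:
            j += 1
        yield i, j, float(values[i])
        i = j


def export_bigwig(c: CoverageDataset, outdir, format: str = "bigwig") -> list[Path]:
    """Write one track file per condition into ``outdir``.

    ``format='bigwig'`` writes .bw via pyBigWig; ``'bedgraph'`` writes the
    numerically identical text dialect.  Returns the written paths.
    """
    if format not in ("bigwig", "bedgraph"):
        raise ValueError(f"unknown track format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ci, cond in enumerate(c.conditions):
        sums, counts = _per_base_accumulate(c, ci)
        entries = []  # (chrom, start, end, value)
        for chrom in sorted(sums):
            covered = counts[chrom] > 0
            vals = np.divide(
                sums[chrom], counts[chrom], out=np.zeros_like(sums[chrom]),
                where=covered,
            )
            for s, e, v in _runs(vals, covered):
                entries.append((chrom, s, e, v))
        if format == "bedgraph":
            path = outdir / f"{cond}.bedgraph"
            with open(path, "w") as fh:
                for chrom, s, e, v in entries:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
        else:
            import pyBigWig

            path = outdir / f"{cond}.bw"
            bw = pyBigWig.open(str(path), "w")
            bw.addHeader([(chrom, c.grid.sizes[chrom]) for chrom in c.grid.sizes])
            if entries:
                bw.addEntries(
                    [e[0] for e in entries],
                    [e[1] for e in entries],
                    ends=[e[2] for e in entries],
                    values=[e[3] for e in entries],
                )
            bw.close()
        paths.append(path)
    return paths


def export_bed(
    c: CoverageDataset, path, threshold: float | None = None, condition: str | None = None
) -> int:
    """Write one BED6 record per bin (score = bin value), optionally only
    bins with value >= ``threshold``.  Returns the record count.

    Multi-condition datasets require selecting a ``condition`` by name.
    """
    if len(c.conditions) > 1 and condition is None:
        raise ValueError(
            f"dataset has conditions {c.conditions}; select one with condition="
        )
    ci = 0 if condition is None else c.conditions.index(condition)
    v = c.values.sum(axis=2)[:, :, ci]
    res = c.resolution
    n = 0
    with open(path, "w") as fh:
        for wi in range(len(c.grid)):
            chrom, fs, _ = c.grid.fetch_range(wi)
            for b in range(c.bins_per_window):
                val = v[wi, b]
                if threshold is not None and val < threshold:
                    continue
                bs, be = fs + b * res, fs + (b + 1) * res
                if bs < 0 or be > c.grid.sizes[chrom]:
                    continue
                fh.write(f"{chrom}\t{bs}\t{be}\tbin_{wi}_{b}\t{val:.10g}\t.\n")
                n += 1
    return n


def align_tracks(
    datasets: Sequence[CoverageDataset], region: GenomicInterval
) -> tuple[np.ndarray, np.ndarray]:
    """Resample each dataset onto the region's per-base axis.

    Returns ``(matrix, positions)`` with one row per dataset-condition in
    input order; each bin's value is repeated over its bases, overlapping
    bins averaged.  A dataset whose grid does not cover every base of the
    region raises ``ValueError``.
    """
    positions = np.arange(region.start, region.end)
    rows = []
    for di, c in enumerate(datasets):
        for ci in range(len(c.conditions)):
            sums, counts = _per_base_accumulate(c, ci)
            if region.chrom not in sums:
                raise ValueError(f"track {di}: no coverage on {region.chrom}")
            cov = counts[region.chrom][region.start : region.end]
            if not (cov > 0).all():
                raise ValueError(
                    f"track {di} ({c.conditions[ci]}): region "
                    f"{region.chrom}:{region.start}-{region.end} not fully covered"
                )
            vals = (
                sums[region.chrom][region.start : region.end] / cov
            )
            rows.append(vals)
    return np.vstack(rows), positions


def plot_tracks(
    datasets: Sequence[CoverageDataset],
    region: GenomicInterval,
    labels: Sequence[str] | None = None,
    path=None,
):
    """Stacked genome-track figure over ``region`` (thin layer over
    :func:`align_tracks`); saved to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix, positions = align_tracks(datasets, region)
    if labels is None:
        labels = [cond for c in datasets for cond in c.conditions]
    fig, axes = plt.subplots(
        len(matrix), 1, sharex=True, figsize=(8, 1.2 * len(matrix)), squeeze=False
    )
    for ax, row, label in zip(axes[:, 0], matrix, labels):
        ax.fill_between(positions, row, step="post", alpha=0.7)
        ax.set_ylabel(label, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel(f"{region.chrom}:{region.start}-{region.end}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
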