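"""Normalization and data-augmentation wrappers for coverage tensors.

Normalizations mirror the options a practitioner applies to binned genomic
read counts before feeding them to a model:

* TPM — per-kilobase rate scaled so each condition's track sums to 1e6;
  the "library" is the set of all bins on the dataset's grid.
* log1p — elementwise natural log(x + 1) (pseudo-count of one).
* z-score — per-condition standardization pooled over windows, bins and
  strands, with population (n) standard deviation; statistics can be fitted
  on training windows and re-applied to held-out windows so no test values
  leak into the statistics.
* z-of-log1p — the composition of the two, the strongest-performing
  normalization for count tracks.

Augmentation is a joint 5'->3' orientation flip: a seeded per-window coin
decides whether a window is presented reverse-complemented, and the same
decision applies to every wrapped dataset (DNA encoding and coverage stay
co-oriented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageDataset
from .encoding import EncodedSequences, revcomp_permutation


@dataclass
class NormalizerSpec:
    """Kind of normalization plus per-condition fitted statistics."""

    kind: str
    mean: np.ndarray | None = None  # per condition
    std: np.ndarray | None = None

    def save(self, path) -> None:
        """Serialize to a small key=value text file for reuse at prediction time."""
        with open(path, "w") as fh:
            fh.write(f"kind={self.kind}\n")
            if self.mean is not None:
                fh.write("mean=" + ",".join(repr(float(x)) for x in self.mean) + "\n")
            if self.std is not None:
                fh.write("std=" + ",".join(repr(float(x)) for x in self.std) + "\n")

    @classmethod
    def load(cls, path) -> "NormalizerSpec":
        kind, mean, std = "none", None, None
        with open(path) as fh:
            for line in fh:
                key, _, val = line.strip().partition("=")
                if key == "kind":
                    kind = val
                elif key == "mean":
                    mean = np.array([float(x) for x in val.split(",")])
                elif key == "std":
                    std = np.array([float(x) for x in val.split(",")])
        return cls(kind, mean, std)


def tpm_values(counts: np.ndarray, lengths_bp: np.ndarray) -> np.ndarray:
    """TPM over arbitrary per-bin lengths: rate_i = count_i / kb_i, scaled
    to sum to 1e6.  All-zero input stays all-zero."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("TPM requires nonnegative counts")
    rate = counts / (np.asarray(lengths_bp, dtype=np.float64) / 1000.0)
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate * 1e6 / total


def tpm_normalize(c: CoverageDataset) -> CoverageDataset:
    """TPM-normalize each condition over all bins of the dataset's grid.

    Every bin spans ``resolution`` bp, so the per-kb rate is
    ``count / (resolution/1000)`` and each condition's output sums to 1e6
    (unless the condition is all zero, which stays zero).
    """
    v = c.values
    if (v < 0).any():
        raise ValueError("TPM requires nonnegative counts")
    kb = c.resolution / 1000.0
    rate = v / kb
    total = rate.sum(axis=(0, 1, 2), keepdims=True)  # per condition
    out = np.divide(rate * 1e6, total, out=np.zeros_like(rate), where=total != 0)
    return c.with_values(out)


def log1p_transform(c: CoverageDataset) -> CoverageDataset:
    """Elementwise log(x + 1)."""
    v = c.values
    if (v < 0).any():
        raise ValueError("log1p requires nonnegative values")
    return c.with_values(np.log1p(v))


def fit_zscore(c: CoverageDataset, window_indices=None, kind: str = "zscore") -> NormalizerSpec:
    """Fit per-condition mean/sd (population) over the given windows only."""
    v = c.values if window_indices is None else c.values[np.asarray(window_indices)]
    mean = v.mean(axis=(0, 1, 2))
    std = v.std(axis=(0, 1, 2))  # population (ddof=0)
    return NormalizerSpec(kind, mean, std)


def zscore(
    c: CoverageDataset, stats: NormalizerSpec | None = None
) -> tuple[CoverageDataset, NormalizerSpec]:
    """Per-condition standardization ``(x - mean) / sd``.

    Supplied ``stats`` (e.g. fitted on training windows) are used verbatim;
    otherwise statistics are fitted over all bins of the input.  Conditions
    with sd = 0 map to all zeros.
    """
    if stats is None:
        stats = fit_zscore(c)
    v = c.values
    std = stats.std
    safe = np.where(std == 0, 1.0, std)
    out = (v - stats.mean) / safe
    out = np.where(std == 0, 0.0, out)
    return c.with_values(out), stats


def zscore_log1p(
    c: CoverageDataset, stats: NormalizerSpec | None = None
) -> tuple[CoverageDataset, NormalizerSpec]:
    """Z score of log(count + 1): log1p then per-condition standardization."""
    logged = log1p_transform(c)
    out, stats = zscore(logged, stats)
    stats.kind = "zscore_log1p"
    return out, stats


NORMALIZERS = ("none", "tpm", "log1p", "zscore", "zscore_log1p")


def normalize(c: CoverageDataset, kind: str) -> CoverageDataset:
    """Dispatch by name; z-score variants fit on the full input."""
    if kind == "none":
        return c
    if kind == "tpm":
        return tpm_normalize(c)
    if kind == "log1p":
        return log1p_transform(c)
    if kind == "zscore":
        return zscore(c)[0]
    if kind == "zscore_log1p":
        return zscore_log1p(c)[0]
    raise ValueError(f"unknown normalization {kind!r}; choose from {NORMALIZERS}")


# ---------------------------------------------------------------------------
# augmentation


def _flip_one(dataset, wi: int, arr: np.ndarray) -> np.ndarray:
    if isinstance(dataset, EncodedSequences):
        perm = revcomp_permutation(dataset.alphabet.k)
        return arr[::-1][:, perm]
    # coverage: reverse bin axis; swap strand channels if present
    flipped = arr[::-1]
    if flipped.shape[1] == 2:
        flipped = flipped[:, ::-1]
    return flipped


class AugmentedView:
    """Joint random 5'->3' orientation flipping over one or more datasets.

    All wrapped datasets must share a grid length.  Flip decisions are drawn
    per window per epoch from a generator seeded by ``seed``; with the same
    seed the flip sequence is identical.  ``flip_prob=0`` is the identity
    view, ``flip_prob=1`` flips every window (useful for tests).
    """

    def __init__(self, datasets, flip_prob: float = 0.5, seed: int = 0):
        self.datasets = list(datasets)
        lengths = {len(d) for d in self.datasets}
        if len(lengths) != 1:
            raise ValueError(f"wrapped datasets disagree on window count: {lengths}")
        self.n_windows = lengths.pop()
        self.flip_prob = float(flip_prob)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self.new_epoch()

    def new_epoch(self) -> None:
        """Redraw per-window flip decisions for a new pass over the data."""
        self.flips = self._rng.random(self.n_windows) < self.flip_prob

    def __len__(self) -> int:
        return self.n_windows

    def batch(self, indices) -> list[np.ndarray]:
        """Materialize the given windows from every wrapped dataset, applying
        the epoch's flip decision jointly."""
        out = []
        for d in self.datasets:
            source = d.tensor if isinstance(d, EncodedSequences) else d.values
            arrs = []
            for wi in indices:
                a = source[wi]
                arrs.append(_flip_one(d, wi, a) if self.flips[wi] else a)
            out.append(np.stack(arrs))
        return out


class BatchIterator:
    """Array-like batching over parallel datasets.

    Iteration yields ``(inputs, targets)`` tuples of fixed-size batches
    (the last batch may be smaller); ``shuffle`` permutes window order
    reproducibly by ``seed`` at each epoch.
    """

    def __init__(self, inputs, targets=None, batch_size: int = 32,
                 shuffle: bool = False, seed: int = 0):
        self.inputs = list(inputs)
        self.targets = list(targets) if targets is not None else []
        lengths = {len(d) for d in self.inputs + self.targets}
        if len(lengths) != 1:
            raise ValueError(f"datasets disagree on window count: {lengths}")
        self.n_windows = lengths.pop()
        self.batch_size = int(batch_size)
        self.shuffle = shuffle
        self.seed = int(seed)
        self._epoch = 0

    def __len__(self) -> int:
        return -(-self.n_windows // self.batch_size)

    def _order(self) -> np.ndarray:
        idx = np.arange(self.n_windows)
        if self.shuffle:
            np.random.default_rng((self.seed, self._epoch)).shuffle(idx)
        return idx

    @staticmethod
    def _take(dataset, idx):
        if isinstance(dataset, AugmentedView):
            return dataset.batch(idx)
        if isinstance(dataset, EncodedSequences):
            return dataset.tensor[idx]
        if isinstance(dataset, CoverageDataset):
            return dataset.values[idx]
        return np.asarray(dataset)[idx]

    def __iter__(self):
        order = self._order()
        for b in range(len(self)):
            idx = order[b * self.batch_size : (b + 1) * self.batch_size]
            ins = [self._take(d, idx) for d in self.inputs]
            tgts = [self._take(d, idx) for d in self.targets]
            yield ins, tgts
        self._epoch += 1


def batch_view(inputs, targets=None, batch_size: int = 32,
               shuffle: bool = False, seed: int = 0) -> BatchIterator:
    """Convenience constructor for :class:`BatchIterator`."""
    return BatchIterator(inputs, targets, batch_size, shuffle, seed)
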