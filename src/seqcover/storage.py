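"""Storage backends and the dataset cache.

A coverage tensor can live as a dense ndarray, a scipy sparse matrix, or an
HDF5 dataset on disk; all three expose the same materialization contract
(``materialize()`` returns the identical dense 4-D array).  The cache keys
built datasets by a digest over source-file fingerprints and every
construction parameter, so a dataset is rebuilt exactly when its inputs or
parameters changed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import h5py
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

BACKENDS = ("ndarray", "sparse", "hdf5")


class DenseBackend:
    kind = "ndarray"

    def __init__(self, values: np.ndarray):
        self._values = np.asarray(values, dtype=np.float64)

    def materialize(self) -> np.ndarray:
        return self._values

    @property
    def shape(self) -> tuple[int, ...]:
        return self._values.shape


class SparseBackend:
    """CSR storage of the tensor flattened to (windows, bins*strands*conditions)."""

    kind = "sparse"

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        self._shape = values.shape
        self._csr = sparse.csr_matrix(values.reshape(values.shape[0], -1))

    def materialize(self) -> np.ndarray:
        return np.asarray(self._csr.todense()).reshape(self._shape)

    @property
    def shape(self) -> tuple[int, ...]:
        return self._shape


class HDF5Backend:
    """File-backed storage; slices are read from disk on materialization."""

    kind = "hdf5"

    def __init__(self, path, name: str = "values", values: np.ndarray | None = None):
        self._path = Path(path)
        self._name = name
        if values is not None:
            with h5py.File(self._path, "a") as fh:
                if name in fh:
                    del fh[name]
                fh.create_dataset(name, data=np.asarray(values, dtype=np.float64))
        with h5py.File(self._path, "r") as fh:
            self._shape = tuple(fh[name].shape)

    def materialize(self) -> np.ndarray:
        with h5py.File(self._path, "r") as fh:
            return fh[self._name][...]

    @property
    def shape(self) -> tuple[int, ...]:
        return self._shape


def make_backend(values: np.ndarray, storage: str, path=None):
    """Wrap a dense tensor in the requested backend kind."""
    if storage == "ndarray":
        return DenseBackend(values)
    if storage == "sparse":
        return SparseBackend(values)
    if storage == "hdf5":
        if path is None:
            raise ValueError("hdf5 storage requires a path")
        return HDF5Backend(path, values=values)
    raise ValueError(f"unknown storage backend {storage!r}; choose from {BACKENDS}")


# ---------------------------------------------------------------------------
# cache


@dataclass(frozen=True)
class CacheKey:
    """Digest over source-file fingerprints and construction parameters."""

    digest: str

    @classmethod
    def build(
        cls,
        files: Iterable[os.PathLike | str],
        params: dict,
        content_hash: bool = False,
    ) -> "CacheKey":
        """Fingerprint ``files`` (size+mtime by default, full content hash
        with ``content_hash=True``) together with ``params``."""
        h = hashlib.sha256()
        for f in sorted(str(f) for f in files):
            p = Path(f)
            h.update(p.name.encode())
            if content_hash:
                h.update(p.read_bytes())
            else:
                st = p.stat()
                h.update(f"{st.st_size}:{st.st_mtime_ns}".encode())
        h.update(json.dumps(params, sort_keys=True, default=str).encode())
        return cls(h.hexdigest())


def save_dataset(dataset, path) -> None:
    """Serialize a CoverageDataset (tensor + grid + metadata) to HDF5."""
    grid = dataset.grid
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=dataset.values)
        fh.create_dataset(
            "window_chroms",
            data=np.array([w.chrom for w in grid], dtype=h5py.string_dtype()),
        )
        fh.create_dataset("window_starts", data=np.array([w.start for w in grid], dtype=np.int64))
        fh.create_dataset(
            "window_strands",
            data=np.array([w.strand for w in grid], dtype=h5py.string_dtype()),
        )
        fh.create_dataset(
            "chrom_names", data=np.array(list(grid.sizes), dtype=h5py.string_dtype())
        )
        fh.create_dataset(
            "chrom_lengths", data=np.array([grid.sizes[c] for c in grid.sizes], dtype=np.int64)
        )
        fh.attrs["binsize"] = grid.binsize
        fh.attrs["stepsize"] = grid.stepsize
        fh.attrs["flank"] = grid.flank
        fh.attrs["resolution"] = dataset.resolution
        fh.attrs["conditions"] = json.dumps(dataset.conditions)
        fh.attrs["stranded"] = dataset.stranded


def load_dataset(path):
    """Inverse of :func:`save_dataset`."""
    from .coverage import CoverageDataset
    from .intervals import BinGrid, ChromSizes, GenomicInterval

    with h5py.File(path, "r") as fh:
        values = fh["values"][...]
        chroms = [c.decode() for c in fh["window_chroms"][...]]
        starts = fh["window_starts"][...]
        strands = [s.decode() for s in fh["window_strands"][...]]
        names = [c.decode() for c in fh["chrom_names"][...]]
        lengths = fh["chrom_lengths"][...]
        binsize = int(fh.attrs["binsize"])
        stepsize = int(fh.attrs["stepsize"])
        flank = int(fh.attrs["flank"])
        resolution = int(fh.attrs["resolution"])
        conditions = json.loads(fh.attrs["conditions"])
        stranded = bool(fh.attrs["stranded"])
    sizes = ChromSizes(dict(zip(names, (int(x) for x in lengths))))
    windows = [
        GenomicInterval(c, int(s), int(s) + binsize, st)
        for c, s, st in zip(chroms, starts, strands)
    ]
    grid = BinGrid(windows, binsize, stepsize, flank, sizes)
    return CoverageDataset.from_values(values, grid, resolution, conditions, stranded)


def load_or_build(key: CacheKey, builder: Callable[[], "object"], cache_dir):
    """Return the cached dataset for ``key`` if present, else invoke
    ``builder``, store its result under the key, and return it.

    A corrupt cache entry is discarded and rebuilt with a warning.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    entry = cache_dir / f"{key.digest}.h5"
    if entry.exists():
        try:
            return load_dataset(entry)
        except Exception:  # corrupt entry: fall through to rebuild
            logger.warning("corrupt cache entry %s: rebuilding", entry)
            entry.unlink(missing_ok=True)
    dataset = builder()
    save_dataset(dataset, entry)
    return dataset
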