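"""Order-k one-hot encoding of biological sequences.

Each position of a length-L DNA sequence encodes the k-mer starting there
over ``4**k`` channels, so an order-k encoding is an ``(L - k + 1, 4**k)``
0/1 matrix; e.g. the di-nucleotide (order-2) encoding of a length-N window
has 16 channels and N - 1 positions.  Channels are ordered lexicographically
over (A, C, G, T).  Any k-mer containing a non-ACGT symbol yields an
all-zero column, so column sums are always 0 or 1.

Protein sequences use the 20 standard amino acids (alphabetical one-letter
codes) at order 1 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

from .intervals import BinGrid, GenomicInterval

DNA = "ACGT"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard amino acids, alphabetical

_DNA_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(DNA):
    _DNA_CODE[ord(_b)] = _i
    _DNA_CODE[ord(_b.lower())] = _i

_PROT_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(PROTEIN):
    _PROT_CODE[ord(_b)] = _i
    _PROT_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (non-ACGT symbols pass through
    complemented where defined, else unchanged)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerAlphabet:
    """An ordered symbol alphabet raised to k-mer order ``k``.

    The channel index of a k-mer is its lexicographic rank:
    ``sum(idx(symbol_j) * n**(k-1-j))`` over positions j, where n is the
    alphabet size.  This is a bijection over unambiguous k-mers.
    """

    letters: str = DNA
    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("order k must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.letters) ** self.k

    def kmer_index(self, kmer: str) -> int:
        """Lexicographic channel index of an unambiguous k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got {kmer!r}")
        n = len(self.letters)
        idx = 0
        for sym in kmer.upper():
            pos = self.letters.find(sym)
            if pos < 0:
                raise ValueError(f"symbol {sym!r} not in alphabet")
            idx = idx * n + pos
        return idx

    def index_to_kmer(self, idx: int) -> str:
        n = len(self.letters)
        out = []
        for _ in range(self.k):
            out.append(self.letters[idx % n])
            idx //= n
        return "".join(reversed(out))


def fetch_sequence(fasta: Fasta, w: GenomicInterval, flank: int = 0) -> str:
    """Fetch the flanked window sequence, uppercased, padded with 'N' where
    the flanked range runs off the chromosome."""
    if w.chrom not in fasta:
        raise KeyError(f"chromosome {w.chrom!r} not in FASTA")
    chrom_len = len(fasta[w.chrom])
    start, end = w.start - flank, w.end + flank
    lo, hi = max(0, start), min(chrom_len, end)
    core = str(fasta[w.chrom][lo:hi]) if hi > lo else ""
    return "N" * (lo - start) + core.upper() + "N" * (end - hi)


def encode_order_k(seq: str, k: int) -> np.ndarray:
    """Order-k one-hot encode a DNA string into ``(L - k + 1, 4**k)``.

    Positions whose k-mer contains an ambiguous symbol are all-zero.
    """
    if k < 1:
        raise ValueError("order k must be >= 1")
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < order {k}")
    codes = _DNA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    P = L - k + 1
    idx = np.zeros(P, dtype=np.int64)
    valid = np.ones(P, dtype=bool)
    for j in range(k):
        cj = codes[j : j + P]
        idx = idx * 4 + np.where(cj >= 0, cj, 0)
        valid &= cj >= 0
    out = np.zeros((P, 4 ** k), dtype=np.int8)
    rows = np.nonzero(valid)[0]
    out[rows, idx[rows]] = 1
    return out


def encode_protein(seq: str) -> np.ndarray:
    """One-hot encode a protein string into ``(L, 20)``; non-standard
    symbols give all-zero rows."""
    codes = _PROT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    out = np.zeros((len(seq), 20), dtype=np.int8)
    rows = np.nonzero(codes >= 0)[0]
    out[rows, codes[rows]] = 1
    return out


def revcomp_permutation(k: int) -> np.ndarray:
    """Channel permutation rho with rho[c] = index of the reverse complement
    of the k-mer with index c.  An involution for every k."""
    alpha = KmerAlphabet(DNA, k)
    perm = np.empty(4 ** k, dtype=np.int64)
    for c in range(4 ** k):
        perm[c] = alpha.kmer_index(revcomp(alpha.index_to_kmer(c)))
    return perm


def revcomp_encoding(M: np.ndarray, k: int) -> np.ndarray:
    """Transform an order-k encoding into that of the reverse-complement
    sequence: reverse the position axis and permute channels."""
    if M.ndim != 2 or M.shape[1] != 4 ** k:
        raise ValueError(f"expected (positions, {4 ** k}) matrix for order {k}")
    perm = revcomp_permutation(k)
    return M[::-1][:, perm]


def decode(M: np.ndarray, k: int) -> str:
    """Invert :func:`encode_order_k`.

    Each base is recovered from any unambiguous overlapping k-mer; bases
    covered by no unambiguous k-mer decode to 'N'.  Overlapping k-mers that
    disagree on a shared base raise ``ValueError``.
    """
    if M.ndim != 2 or M.shape[1] != 4 ** k:
        raise ValueError(f"expected (positions, {4 ** k}) matrix for order {k}")
    alpha = KmerAlphabet(DNA, k)
    P = M.shape[0]
    L = P + k - 1
    bases: list[str | None] = [None] * L
    for i in range(P):
        ones = np.nonzero(M[i])[0]
        if ones.size == 0:
            continue
        if ones.size > 1:
            raise ValueError(f"position {i}: more than one active channel")
        kmer = alpha.index_to_kmer(int(ones[0]))
        for j, b in enumerate(kmer):
            if bases[i + j] is None:
                bases[i + j] = b
            elif bases[i + j] != b:
                raise ValueError(
                    f"inconsistent overlapping k-mers at base {i + j}: "
                    f"{bases[i + j]} vs {b}"
                )
    return "".join(b if b is not None else "N" for b in bases)


@dataclass
class EncodedSequences:
    """Per-window order-k one-hot tensors over a :class:`BinGrid`.

    ``tensor`` has shape ``(num_windows, L - k + 1, 4**k)`` with
    ``L = binsize + 2 * flank``.  Windows on the minus strand are encoded
    from the reverse-complement sequence; '.' is treated as '+'.
    """

    tensor: np.ndarray
    alphabet: KmerAlphabet
    grid: BinGrid = field(repr=False)

    @classmethod
    def from_fasta(cls, fasta_path, grid: BinGrid, k: int = 1) -> "EncodedSequences":
        fasta = Fasta(str(fasta_path))
        mats = []
        for w in grid:
            seq = fetch_sequence(fasta, w, grid.flank)
            if w.strand == "-":
                seq = revcomp(seq)
            mats.append(encode_order_k(seq, k))
        L = grid.window_length
        tensor = (
            np.stack(mats)
            if mats
            else np.zeros((0, L - k + 1, 4 ** k), dtype=np.int8)
        )
        return cls(tensor, KmerAlphabet(DNA, k), grid)

    def __len__(self) -> int:
        return self.tensor.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tensor.shape

    def __getitem__(self, i):
        return self.tensor[i]

    def to_hdf5(self, path, name: str = "encoded") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            ds = fh.create_dataset(name, data=self.tensor, compression="gzip")
            ds.attrs["order"] = self.alphabet.k
            ds.attrs["alphabet"] = self.alphabet.letters
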