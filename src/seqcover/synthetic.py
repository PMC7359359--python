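"""Deterministic synthetic genomics data for tests and walkthroughs.

Everything downstream — FASTA genomes with planted transcription-factor
motifs, SAM alignments, bedGraph tracks, narrowPeak calls, VCFs, and a
differentiable toy motif predictor — is generated from explicit seeds, so
the whole framework is exercisable without any external download.  The
default planted motif is TGACTCA, the canonical AP-1/JunD binding site.

Generators are pure functions of their seed and parameters: the same call
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import DNA, encode_order_k, revcomp, decode
from .intervals import ChromSizes, GenomicInterval, RegionSet

JUND_MOTIF = "TGACTCA"


@dataclass
class SyntheticGenome:
    """Random genome with exact-match motif plants at known positions."""

    sequences: dict[str, str]
    sizes: ChromSizes
    motif: str
    plants: list[tuple[str, int]]  # (chrom, 0-based start of motif)

    def fasta_text(self, width: int = 70) -> str:
        out = []
        for chrom, seq in self.sequences.items():
            out.append(f">{chrom}")
            for i in range(0, len(seq), width):
                out.append(seq[i : i + width])
        return "\n".join(out) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fasta_text())


def _find_all(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def make_genome(
    seed: int,
    chrom_lengths: dict[str, int],
    motif: str = JUND_MOTIF,
    n_plants: int = 0,
    max_tries: int = 200,
) -> SyntheticGenome:
    """Uniform-random ACGT genome with exactly ``n_plants`` exact motif
    occurrences at recorded, non-overlapping positions.

    Accidental background occurrences of the motif (or its reverse
    complement) are removed by re-randomizing the colliding stretch, so the
    returned plant list is the complete occurrence list.
    """
    motif = motif.upper()
    for chrom, length in chrom_lengths.items():
        if length <= len(motif):
            raise ValueError(f"chromosome {chrom} shorter than motif")
    rng = np.random.default_rng(seed)
    rc = revcomp(motif)
    seqs: dict[str, list[str]] = {}
    for chrom, length in chrom_lengths.items():
        seq = "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])
        for _ in range(max_tries):
            hits = sorted(set(_find_all(seq, motif)) | set(_find_all(seq, rc)))
            if not hits:
                break
            for h in hits:
                repl = "".join(np.array(list(DNA))[rng.integers(0, 4, size=len(motif))])
                seq = seq[:h] + repl + seq[h + len(motif) :]
        else:
            raise RuntimeError("could not scrub background motif occurrences")
        seqs[chrom] = seq
    # plant motifs at random non-overlapping positions across chromosomes
    plants: list[tuple[str, int]] = []
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    if n_plants * 2 * len(motif) > total:
        raise ValueError("infeasible number of motif plants")
    for _ in range(max_tries):
        plants = []
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        probs = np.array([chrom_lengths[c] for c in chroms], dtype=float) / total
        ok = True
        for _i in range(n_plants):
            for _try in range(max_tries):
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                pos = int(rng.integers(0, chrom_lengths[chrom] - len(motif)))
                if all(
                    pos + len(motif) <= s or pos >= e for s, e in occupied[chrom]
                ):
                    occupied[chrom].append((pos, pos + len(motif)))
                    plants.append((chrom, pos))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        candidate = dict(seqs)
        for chrom, pos in plants:
            s = candidate[chrom]
            candidate[chrom] = s[:pos] + motif + s[pos + len(motif) :]
        # planting may create spurious junction matches; verify and retry
        clean = True
        for chrom in chroms:
            expected = sorted(p for c, p in plants if c == chrom)
            if _find_all(candidate[chrom], motif) != expected:
                clean = False
            if any(
                h not in expected for h in _find_all(candidate[chrom], rc)
            ) and motif != rc:
                clean = False
        if clean:
            seqs = candidate
            break
    else:
        raise RuntimeError("could not plant motifs without collisions")
    plants.sort()
    return SyntheticGenome(seqs, ChromSizes(chrom_lengths), motif, plants)


def make_alignments(
    genome: SyntheticGenome,
    regions: RegionSet,
    depth: int,
    read_len: int,
    seed: int,
) -> tuple[str, list[tuple[str, int, str]]]:
    """Place ``depth`` reads uniformly (random strand) within each region.

    Returns valid SAM text plus the (chrom, 5'-end position, strand) of
    every read for oracle pileups.  The 5' end of a minus-strand read is
    its rightmost aligned base.
    """
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom in genome.sizes:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome.sizes[chrom]}")
    five_primes: list[tuple[str, int, str]] = []
    n = 0
    for region in regions:
        if read_len > len(region):
            raise ValueError(
                f"read_len {read_len} exceeds region length {len(region)}"
            )
        for _ in range(depth):
            start = int(rng.integers(region.start, region.end - read_len + 1))
            minus = bool(rng.integers(0, 2))
            seq = genome.sequences[region.chrom][start : start + read_len]
            flag = 16 if minus else 0
            if minus:
                seq = revcomp(seq)
                five_primes.append((region.chrom, start + read_len - 1, "-"))
            else:
                five_primes.append((region.chrom, start, "+"))
            lines.append(
                f"read{n}\t{flag}\t{region.chrom}\t{start + 1}\t60\t"
                f"{read_len}M\t*\t0\t0\t{seq}\t*"
            )
            n += 1
    return "\n".join(lines) + "\n", five_primes


def make_track(profile: list[tuple[GenomicInterval, float]]) -> str:
    """bedGraph text from (interval, value) blocks; gaps stay implicit."""
    records = sorted(profile, key=lambda p: (p[0].chrom, p[0].start))
    return "".join(
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:.10g}\n" for iv, value in records
    )


def make_peaks(
    motif_positions: list[tuple[str, int]],
    peak_halfwidth: int,
    sizes: ChromSizes,
    motif_len: int = len(JUND_MOTIF),
) -> str:
    """narrowPeak text with one peak centered on each planted motif."""
    lines = []
    for i, (chrom, pos) in enumerate(sorted(motif_positions)):
        center = pos + motif_len // 2
        start = max(0, center - peak_halfwidth)
        end = min(sizes[chrom], center + peak_halfwidth)
        summit = center - start
        lines.append(
            f"{chrom}\t{start}\t{end}\tpeak{i}\t500\t.\t5.0\t-1\t-1\t{summit}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def make_vcf(variants, sizes: ChromSizes) -> str:
    """Minimal VCF 4.2 text for (chrom, pos_1based, id, ref, alt) tuples."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sizes:
        lines.append(f"##contig=<ID={chrom},length={sizes[chrom]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, vid, ref, alt in variants:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# toy predictors


def _sigmoid(z: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


class ToyMotifPredictor:
    """Differentiable motif-match scorer over order-1 one-hot encodings.

    The motif's one-hot matrix M is correlated with the input at every
    offset; an exact match gives correlation L (motif length).  The soft
    match count ``m(x) = sum_i 2*relu(corr_i - (L - 0.5))`` equals the
    exact-match count on one-hot inputs (the 0.5 margin keeps every
    integer-valued correlation away from the ReLU kink, so the analytic
    gradient matches finite differences there), and the score is
    ``sigmoid(a*m + b)``.
    """

    def __init__(self, motif: str = JUND_MOTIF, a: float = 4.0, b: float = -2.0):
        self.motif = motif.upper()
        self.M = encode_order_k(self.motif, 1).astype(np.float64)  # (L, 4)
        self.a = float(a)
        self.b = float(b)

    def _corr(self, x: np.ndarray) -> np.ndarray:
        """corr[i] = <M, x[i:i+L]> for each offset i."""
        L = len(self.motif)
        P = x.shape[0]
        if P < L:
            return np.zeros(0)
        return np.array(
            [float((self.M * x[i : i + L]).sum()) for i in range(P - L + 1)]
        )

    def match_count(self, x: np.ndarray) -> float:
        c = self._corr(np.asarray(x, dtype=np.float64))
        return float(np.sum(2.0 * np.maximum(c - (len(self.motif) - 0.5), 0.0)))

    def score_one(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.a * self.match_count(x) + self.b))

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 2:
            batch = batch[None]
        return np.array([self.score_one(x) for x in batch])

    def grad(self, x: np.ndarray) -> np.ndarray:
        """Exact gradient of the score w.r.t. the encoding."""
        x = np.asarray(x, dtype=np.float64)
        c = self._corr(x)
        m = float(np.sum(2.0 * np.maximum(c - (len(self.motif) - 0.5), 0.0)))
        s = _sigmoid(self.a * m + self.b)
        outer = float(s * (1 - s) * self.a)
        g = np.zeros_like(x)
        L = len(self.motif)
        for i in np.nonzero(c > L - 0.5)[0]:
            g[i : i + L] += 2.0 * self.M
        return outer * g


class MotifCountPredictor:
    """Exact-match motif counter over decoded order-k encodings.

    Not differentiable; the reference oracle for variant-effect examples
    (destroying one planted motif changes the count by exactly -1).
    """

    def __init__(self, motif: str = JUND_MOTIF, k: int = 1):
        self.motif = motif.upper()
        self.k = k

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        if batch.ndim == 2:
            batch = batch[None]
        return np.array(
            [float(len(_find_all(decode(np.asarray(x), self.k), self.motif))) for x in batch]
        )


def toy_predictor(
    motif: str = JUND_MOTIF, a: float = 4.0, b: float = -2.0
) -> ToyMotifPredictor:
    """Sigmoid motif predictor with an exact analytic gradient."""
    return ToyMotifPredictor(motif, a, b)
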