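"""Variant-effect scoring, integrated-gradients attribution, and metrics.

Variant effects for SNVs are scored by embedding the reference and the
alternative allele in an identical sequence context: a window centered on
the variant is fetched, order-k one-hot encoded for both alleles (an
interior SNV changes exactly k overlapping k-mer columns), and a
user-supplied predictor maps both encodings to scores.  Reported per model
output are the two scores, their difference and the logit difference.

Integrated gradients attribute a scalar prediction to input features by
averaging gradients along the straight path from a baseline to the input;
the completeness residual |sum(attributions) - (f(x) - f(baseline))| is
reported alongside and shrinks as the number of integration steps grows
(and is zero for affine predictors).

Metrics: the precision-recall curve with the step-wise (average-precision)
area rule, preferred over ROC for the heavy class imbalance of peak
prediction, and Pearson correlation for regression tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from pyfaidx import Fasta

from .encoding import encode_order_k

logger = logging.getLogger(__name__)

_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.id}: ref/alt must be single unambiguous bases")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref == alt")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass
class VariantScore:
    """Per-SNV, per-model-output ref/alt predictions."""

    variant: VariantRecord
    ref_score: np.ndarray  # (n_outputs,)
    alt_score: np.ndarray
    diff: np.ndarray = field(init=False)
    logodds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ref_score = np.atleast_1d(np.asarray(self.ref_score, dtype=np.float64))
        self.alt_score = np.atleast_1d(np.asarray(self.alt_score, dtype=np.float64))
        self.diff = self.alt_score - self.ref_score
        eps = 1e-6
        a = np.clip(self.alt_score, eps, 1 - eps)
        r = np.clip(self.ref_score, eps, 1 - eps)
        self.logodds = np.log(a / (1 - a)) - np.log(r / (1 - r))


def read_vcf_snvs(path) -> list[VariantRecord]:
    """Parse SNV records from a VCF 4.x file.

    Indels and multi-allelic records are skipped (count logged).  Positions
    stay 1-based here and convert at sequence access.
    """
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                skipped += 1
                continue
            records.append(
                VariantRecord(
                    rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper(), rec.id or "."
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-SNV/multi-allelic records", path, skipped)
    return records


def variant_effect(
    fasta,
    variants,
    predictor,
    window: int,
    k: int = 1,
) -> list[VariantScore]:
    """Score each SNV with ``predictor`` over a centered sequence window.

    The window of length ``window`` places the variant base at offset
    ``window // 2``; the alt encoding substitutes the alternative base,
    which for an interior variant changes exactly k overlapping k-mer
    columns of the order-k encoding.  ``predictor`` receives a batch of
    shape ``(n, window - k + 1, 4**k)`` and returns ``(n, n_outputs)`` or
    ``(n,)`` scores.  A variant whose stated reference base disagrees with
    the FASTA raises, naming the variant.
    """
    if window < k:
        raise ValueError("window must be >= k")
    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta))
    scores: list[VariantScore] = []
    for var in variants:
        center = window // 2
        start = var.pos0 - center
        seq = _fetch_span(fasta, var.chrom, start, start + window)
        if seq[center] != var.ref:
            raise ValueError(
                f"variant {var.id} at {var.chrom}:{var.pos}: reference base "
                f"is {seq[center]!r}, VCF says {var.ref!r}"
            )
        alt_seq = seq[:center] + var.alt + seq[center + 1 :]
        batch = np.stack([encode_order_k(seq, k), encode_order_k(alt_seq, k)]).astype(
            np.float64
        )
        out = np.asarray(predictor(batch), dtype=np.float64)
        if out.ndim == 1:
            out = out[:, None]
        scores.append(VariantScore(var, out[0], out[1]))
    return scores


def _fetch_span(fasta: Fasta, chrom: str, start: int, end: int) -> str:
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} not in FASTA")
    chrom_len = len(fasta[chrom])
    lo, hi = max(0, start), min(chrom_len, end)
    core = str(fasta[chrom][lo:hi]).upper() if hi > lo else ""
    return "N" * (lo - start) + core + "N" * (end - hi)


def variant_scores_to_tsv(scores, path) -> None:
    """Write one row per (variant, model output)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\tref\talt\toutput\tref_score\talt_score\tdiff\tlogodds\n")
        for s in scores:
            for oi in range(len(s.ref_score)):
                fh.write(
                    f"{s.variant.chrom}\t{s.variant.pos}\t{s.variant.id}\t"
                    f"{s.variant.ref}\t{s.variant.alt}\t{oi}\t"
                    f"{s.ref_score[oi]:.10g}\t{s.alt_score[oi]:.10g}\t"
                    f"{s.diff[oi]:.10g}\t{s.logodds[oi]:.10g}\n"
                )


# ---------------------------------------------------------------------------
# integrated gradients


@dataclass
class Attribution:
    """Per-feature attributions for one window and one scalar output."""

    values: np.ndarray
    baseline: np.ndarray
    steps: int
    completeness_residual: float


def integrated_gradients(
    f,
    grad,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
) -> Attribution:
    """Riemann-sum integrated gradients along the straight path from
    ``baseline`` (default all-zero) to ``x``.

    ``attribution = (x - baseline) * mean_s grad(baseline + (s/m)(x - baseline))``
    for s = 1..m.  Exact for affine ``f`` at any m; for smooth nonlinear f
    the completeness residual decays as m grows.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != x.shape:
        raise ValueError(f"baseline shape {baseline.shape} != input shape {x.shape}")
    delta = x - baseline
    total = np.zeros_like(x)
    for s in range(1, steps + 1):
        total += np.asarray(grad(baseline + (s / steps) * delta), dtype=np.float64)
    attr = delta * total / steps
    residual = abs(float(attr.sum()) - (float(f(x)) - float(f(baseline))))
    return Attribution(attr, baseline, steps, residual)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class PRCurve:
    """Precision-recall points in threshold-descending order, plus area."""

    recall: np.ndarray
    precision: np.ndarray
    area: float


def pr_curve(labels, scores) -> PRCurve:
    """Precision-recall curve with the step-wise average-precision area.

    Points are computed at every distinct score threshold (descending, ties
    grouped); ``area = sum_t (R_t - R_{t-1}) * P_t``.  Linear interpolation
    in PR space is deliberately not used (it overestimates the area).
    Raises if there is no positive label.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D vectors")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("auPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # last index of each distinct-threshold group
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(sorted_scores) - 1]
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / n_pos
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRCurve(recall, precision, area)


def auprc(labels, scores) -> float:
    return pr_curve(labels, scores).area


def pearson(x, y) -> float:
    """Product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    from scipy import stats

    return float(stats.pearsonr(x, y).statistic)


def metrics_to_tsv(metrics: dict, path) -> None:
    """Write a {name: value} metrics table."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in metrics.items():
            fh.write(f"{name}\t{value:.10g}\n")
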