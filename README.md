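# seqcover

Genomic dataset objects for deep learning in regulatory genomics.

Deep models of the epigenome — transcription-factor binding, chromatin
accessibility, promoter activity — all consume the same kinds of input: DNA
sequence one-hot encodings and binned coverage signal over a set of genomic
windows. Most of the engineering effort in such projects goes into turning
FASTA, BED/narrowPeak/GFF, SAM/BAM and bigWig/bedGraph files into
model-ready numeric tensors, and turning prediction arrays back into
genome-browser tracks. `seqcover` packages that data layer, independent of
any particular model library:

- **Regions and windows.** A region of interest (ROI) is built from
  BED-like files by interval arithmetic (extend by *E* bp, merge, subtract
  a blacklist) and tiled into fixed-size windows with `binsize`, `stepsize`
  and a symmetric `flank` applied at fetch time. Windows are labeled by
  any-overlap with peak calls and partitioned by chromosome for
  train/validation/test splits.
- **Higher-order one-hot encoding.** Position *i* of a length-*N* window
  encodes the *k*-mer starting there over 4^*k* lexicographic channels, so
  the order-2 (di-nucleotide) encoding is a 16 × (*N* − 1) matrix with a
  single 1 per unambiguous column. Reverse-complement transforms operate
  directly on encodings (a channel permutation plus position reversal), and
  protein sequences are supported at order 1 over the 20 amino acids.
- **Binned coverage.** `(windows × bins × strands × conditions)` tensors
  from BAM (5′-end counting), bigWig/bedGraph (per-base aggregation) and
  BED (binary/score/count rasterization), at any resolution dividing the
  window, with dense / sparse / HDF5 storage backends and a
  content-fingerprint cache.
- **Normalization and augmentation.** TPM (per-kb rate scaled to 10⁶ per
  condition), log(x+1), and z-score of log(count+1) with statistics fitted
  on training windows only; joint, seeded 5′→3′ orientation flipping of
  sequence and coverage; an array-like batching view.
- **Evaluation and interpretation.** auPRC via the step-wise
  average-precision rule, Pearson correlation, SNV variant-effect scoring
  (ref/alt windows through any predictor callable; difference and
  log-odds difference per output), and integrated-gradients attribution
  with its completeness residual.
- **Export.** Prediction arrays re-anchored to the genome and written as
  bigWig/bedGraph/BED tracks, plus stacked genome-track plotting.

A `seqcover.synthetic` module generates complete miniature studies —
genomes with planted TGACTCA (AP-1/JunD) motifs, peak calls, SAM
alignments, tracks, VCFs and a differentiable toy motif predictor — so the
whole pipeline runs and is tested without any external download.

## Worked example

A miniature binding-site study: plant 12 motifs in a 65-kb genome, build
the ROI as the union of peaks ± 1 kb, tile into 200-bp bins with a 150-bp
sequence flank and a 450-bp coverage flank, and evaluate a toy motif
predictor.

```python
import numpy as np
from pathlib import Path
from seqcover import *
from seqcover.synthetic import make_genome, make_peaks, make_alignments, toy_predictor
from seqcover.transforms import zscore_log1p

work = Path("demo"); work.mkdir(exist_ok=True)
genome = make_genome(seed=1, chrom_lengths={"chr1": 30000, "chr2": 20000,
                                            "chr3": 15000}, n_plants=12)
genome.write(work / "genome.fa")
(work / "peaks.narrowPeak").write_text(make_peaks(genome.plants, 100, genome.sizes))

peaks = read_regions(work / "peaks.narrowPeak", "narrowpeak", genome.sizes)
roi = extend_and_merge(peaks, 1000)            # union of peaks +- 1 kb
grid = tile(roi, binsize=200, stepsize=200, flank=150)
labels = label_by_overlap(grid, peaks)
print(f"{len(grid)} windows of {grid.window_length} bp, {labels.sum()} labeled positive")

dna = EncodedSequences.from_fasta(work / "genome.fa", grid, k=2)
print("order-2 encoding tensor:", dna.shape)

sam, _ = make_alignments(genome, roi, depth=25, read_len=36, seed=2)
(work / "reads.sam").write_text(sam)
dnase_grid = tile(roi, 200, 200, flank=450)
dnase = coverage_from_bam(work / "reads.sam", dnase_grid, resolution=50)
dnase_z, stats = zscore_log1p(dnase)
print("DNase tensor:", dnase.shape,
      f"-> z-of-log1p mean {dnase_z.values.mean():.2g}, sd {dnase_z.values.std():.2f}")

pred = toy_predictor(genome.motif)
scores = pred(EncodedSequences.from_fasta(work / "genome.fa", grid, k=1)
              .tensor.astype(float))
print(f"auPRC = {auprc(labels, scores):.3f} (prevalence {labels.mean():.3f})")

flat = tile(roi, 200, 200, flank=0)
track, = export_bigwig(dataset_from_array(np.asarray(scores), flat,
                                          resolution=200), work / "tracks")
print("wrote", track.name)
```

Output:

```
118 windows of 500 bp, 15 labeled positive
order-2 encoding tensor: (118, 499, 16)
DNase tensor: (118, 22, 1, 1) -> z-of-log1p mean 1.5e-16, sd 1.00
auPRC = 0.455 (prevalence 0.127)
wrote c0.bw
```

The 118 × 499 × 16 tensor is the di-nucleotide encoding of the 500-bp
sequence windows (200-bp bin ± 150 bp); the coverage tensor bins an
1100-bp window (± 450 bp) into 22 bins of 50 bp, standardized by z-of-log1p
to mean 0 / sd 1. The toy predictor, which only fires on exact motif
matches anywhere in the flanked window, ranks bins far above the 0.127
prevalence baseline; its per-window scores are exported as a bigWig track
aligned to the unflanked bins.

The same pipeline is available from the shell:

```bash
seqcover fixtures --seed 5 --outdir demo
seqcover encode --fasta demo/genome.fa --roi demo/peaks.narrowPeak \
    --roi-format narrowpeak --chrom-sizes demo/genome.chrom.sizes \
    --binsize 200 --flank 150 --order 2 --out demo/dna.h5
seqcover coverage --input demo/reads.sam --roi demo/peaks.narrowPeak \
    --roi-format narrowpeak --chrom-sizes demo/genome.chrom.sizes \
    --binsize 200 --flank 450 --resolution 50 --normalize zscore_log1p \
    --out demo/dnase.h5
```

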