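# Methods

This note records the conventions, definitions and design choices behind
`seqcover`, in the order data flows through the package.

## Coordinates, regions and windows

All internal coordinates are 0-based half-open (BED convention). GFF input
is converted at the reader boundary (`start-1`, `end`); BED, narrowPeak and
bedGraph coordinates are taken verbatim. Every `RegionSet` is bound to a
`ChromSizes` table and sorted by `(chrom, start, end)`; records on unknown
chromosomes are rejected by name, malformed lines are reported with their
line number.

The ROI-construction idiom is `extend_and_merge(peaks, E)` — extend each
peak by `E` bp on both sides, clip to chromosome bounds, merge overlapping
or bookended intervals — optionally followed by `subtract(roi, blacklist)`.
Merging drops strand and score (a union of peaks is unstranded).

`tile(roi, binsize, stepsize, flank)` anchors windows at each ROI
interval's start and emits starts `s, s+stepsize, …` while
`start + binsize <= interval.end`; intervals shorter than `binsize` yield
no windows (logged, not fatal). There is no global tiling phase: anchoring
at the interval start is the simplest reproducible rule. The `flank` is
recorded on the grid and applied only at data-fetch time, so window
identity (and labels) never depend on it; the effective fetch range of a
window is `[start - flank, end + flank)`, which may run off the chromosome.
Out-of-bounds positions are padded — `N` for sequence, 0 for coverage — so
every window yields a fixed-shape tensor.

`label_by_overlap` is binary any-overlap: a window is positive iff it
shares at least one base with a peak, with no minimum-overlap fraction.
`split_by_chromosome` assigns each window to the partition naming its
chromosome, with every unnamed chromosome going to the training partition;
a chromosome named in two partitions is an error.

Intervals on strand `.` are treated as `+` wherever orientation matters.

## Sequence encoding

The order-k one-hot encoding of a length-L window is an
`(L - k + 1, 4^k)` 0/1 matrix: position `i` carries a single 1 in the
channel of the k-mer `seq[i:i+k]`, with channels ordered lexicographically
over `(A, C, G, T)` (`AA=0, AC=1, …, TT=15` at k=2). Any k-mer containing a
non-ACGT symbol yields an all-zero column, preserving the {0,1} tensor and
the single-1 property where defined; fractional IUPAC expansion is
deliberately not offered. Soft-masked (lowercase) sequence is uppercased
and otherwise treated normally.

The reverse-complement of an encoding is computed without re-encoding:
reverse the position axis and apply the channel permutation
`rho(c) = index(revcomp(kmer(c)))`, which is an involution for every k.
`decode` inverts the encoding, recovering each base from any unambiguous
overlapping k-mer (`N` where none covers it) and rejecting inconsistent
overlaps.

Protein sequences are encoded at order 1 over the 20 standard amino acids
in alphabetical one-letter order; non-standard symbols give zero rows.

The logical tensor layout is `(window, position, channel)`; adapters to a
particular model library's expected layout are the consumer's concern.
Minus-strand windows are encoded from the reverse-complement sequence.

## Coverage

Tensors have axes `(window, bin, strand, condition)` with
`bins_per_window = (binsize + 2*flank) / resolution`, which must divide
exactly. One condition per input file, named after the file basename.

- **Alignments** (SAM or BAM, streamed; no index required): each retained
  read contributes a count of 1 at the bin containing its 5′ end — the
  leftmost aligned base for forward reads, the rightmost for reverse
  reads. This single-base assignment is the standard convention for
  cleavage assays such as DNase-seq; full-read pileup and
  fragment-extension modes are out of scope. Unmapped reads and reads
  below `min_mapq` (default 0) are skipped; mates of a pair count
  independently; duplicates are retained.
- **Tracks** (bigWig, or bedGraph text as an equivalent dialect): per-base
  values aggregated per bin by sum (default) or mean, with missing/NaN
  bases read as 0 rather than NaN so tensors stay finite.
- **Intervals** (BED/narrowPeak/GFF, format sniffed or given): `binary`
  (any overlap), `score` (max overlapping record score, 0 if none;
  rejected for BED3, which has no score column), or `count` (number of
  overlapping records). At `resolution = binsize` and zero flank, binary
  mode reproduces `label_by_overlap` exactly.

Storage backends — dense ndarray, scipy CSR on the flattened window axis,
and HDF5 file-backed — materialize identical values; the choice trades
memory for speed. The cache keys a built dataset by a SHA-256 digest over
the source files (size + mtime by default, full content hash on request)
and every construction parameter; a digest match loads the stored tensor
without rebuilding, any change rebuilds, and a corrupt entry is discarded
with a warning.

## Normalization and augmentation

- **TPM**: per condition, `rate_i = count_i / (bin length in kb)`, scaled
  so the condition sums to 10⁶. The "library" is all bins of the dataset's
  grid — TPM on binned genomic coverage needs a denominator, and the
  loaded ROI is the natural one. All-zero conditions stay zero.
- **log1p**: elementwise natural `log(x + 1)` (pseudo-count of one).
- **z-score**: per condition, pooled over windows, bins and strands, using
  the population (n) standard deviation; sd = 0 maps to 0. Statistics are
  global rather than per-chromosome. `fit_zscore(ds, train_indices)` fits
  on training windows only, and the returned `NormalizerSpec` (serializable
  to a key=value text file) re-applies the same affine map to held-out
  data, so no test values ever enter the statistics.
- **z-of-log1p** is the literal composition of the two.

Orientation augmentation flips a window's 5′→3′ orientation with
probability `p` per window per epoch, drawn from a seeded generator:
coverage reverses its bin axis and swaps strand channels, sequence
encodings reverse-complement, and one decision applies jointly to all
wrapped datasets so DNA and coverage stay co-oriented. `batch_view`
provides length, shape, indexed access and seeded-shuffle batch iteration
over parallel datasets.

## Export

Prediction arrays are re-anchored with `dataset_from_array` and written one
track per condition. The exported per-base value is the mean over all bins
covering that base — the only order-independent resolution for overlapping
stepped windows — and bases covered by no window are absent from the file.
Out-of-bounds (flank) bins are not exported. bedGraph text is a first-class
output dialect with numerically identical content to bigWig.
`align_tracks` resamples datasets onto a region's per-base axis (bin values
repeated over their bases, overlaps averaged) and errors for any track that
does not fully cover the region; plotting is a thin matplotlib layer over
that matrix.

## Variant effect and attribution

SNVs are read from VCF 4.x (1-based positions kept until sequence access);
indels and multi-allelic records are skipped with a logged count, and
ref == alt records are invalid. Each variant is embedded at offset
`window // 2` of a centered window; the alt encoding substitutes the
alternative base, changing exactly `min(k, distance-to-edge)` k-mer columns
of the order-k encoding. A predictor callable maps the ref/alt batch to
scores; reported per output are both scores, `diff = alt - ref`, and the
logit difference with scores clipped into `[1e-6, 1 - 1e-6]` to avoid
infinities on saturated predictors. A reference-base mismatch against the
FASTA is an error naming the variant.

Integrated gradients use the right-endpoint Riemann sum over the straight
path from the baseline (default all-zero, the natural "no sequence"
encoding) to the input:
`attr = (x - b) * mean_{s=1..m} grad(b + (s/m)(x - b))`. The completeness
residual `|sum(attr) - (f(x) - f(b))|` is stored on the result; it is zero
for affine predictors at any m and decays roughly as 1/m for piecewise-
smooth ones — non-monotonically between nearby step counts when the path
crosses a kink, which the tests account for by comparing well-separated
step counts. Attribution operates on one window and one scalar output;
batching is the caller's loop.

## Metrics

auPRC uses the step-wise average-precision rule: thresholds at every
distinct score (descending, ties grouped),
`area = sum_t (R_t - R_{t-1}) * P_t`. Trapezoidal interpolation in PR space
is deliberately avoided (it is optimistically biased); the implementation
is cross-checked in the tests against exhaustive threshold enumeration and
against scikit-learn's `average_precision_score`, which is never used as
the implementation. The curve is undefined (an error) without positive
labels. Pearson correlation delegates to `scipy.stats.pearsonr` after
rejecting zero-variance input.

## Synthetic data

`make_genome` draws a uniform ACGT background, scrubs every accidental
occurrence of the motif and its reverse complement by re-randomizing the
colliding stretch, then plants the motif at random non-overlapping
positions and verifies the final occurrence list equals the plant list —
so planted positions are the complete ground truth. `make_alignments`
places fixed-length reads uniformly within regions at random strand and
returns the 5′-end list alongside the SAM text, giving an independent
pileup oracle. `make_peaks` centers one narrowPeak record on each plant;
`make_track` and `make_vcf` write bedGraph and VCF text.

The toy predictor scores a window by
`sigmoid(a * m(x) + b)` where `m(x) = sum_i 2*relu(corr_i - (L - 0.5))`,
`corr_i` being the correlation of the motif's one-hot matrix with the
encoding at offset `i`. On one-hot inputs `m` equals the exact-match count,
and the 0.5 margin keeps integer-valued correlations away from the ReLU
kink so the analytic gradient matches finite differences everywhere the
tests probe. A separate non-differentiable `MotifCountPredictor` counts
exact matches on decoded windows and serves as the variant-effect oracle
(destroying a planted motif changes its output by exactly −1).

What the generator does *not* emulate: read errors, fragment-length and GC
biases, duplicate structure, chromatin-driven nonuniform backgrounds, and
degenerate (PWM-like) motif instances. Passing tests therefore demonstrate
the correctness of the data transformations and metrics under controlled
conditions, not model performance on real assays.

## Problem sizes

The default test study uses a 65-kb three-chromosome genome with 6–12
planted motifs, depth-25 alignments and ~120 windows; the acceptance script
uses the same scale. These sizes exercise every code path — multiple
chromosomes, overlapping peaks, out-of-bounds flanks — while keeping the
full suite and the acceptance run in seconds.

## Known limitations

- BAM ingestion streams the whole file rather than using indexed random
  access; for desk-scale ROIs this is simpler and fast, but genome-scale
  BAMs would benefit from indexed fetch per contig.
- bigWig bin aggregation offers sum and mean only (default sum);
  quantile/GC normalizations are out of scope.
- Spliced (RNA-seq) coverage, fragment-midpoint counting and liftover are
  not supported.
- `align_tracks` requires full coverage of the requested region per track.
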