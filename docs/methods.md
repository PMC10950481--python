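# Methods

## Model

A core promoter element is represented by a position weight matrix (PWM)
`P(i, j)`: for each motif position `j = 1..L`, the probability of observing
nucleotide `i ∈ {A, C, G, T}`. Detection is by the log-likelihood-ratio
score of a sequence window `w` against a single-nucleotide background:

    S(w) = Σ_j log2( P(w_j, j) / b(w_j) )        [bits]

The background is parameterized by a single GC fraction `gc`:
`b(G) = b(C) = gc/2` and `b(A) = b(T) = (1 − gc)/2`. This corrects for
base-composition bias: in a GC-poor genome an AT-rich motif is less
surprising, and its scores shrink accordingly. `gc` may be given explicitly
or estimated from the input sequences (pooled G+C over A+C+G+T, ambiguous
bases excluded). `gc` of exactly 0 or 1 is rejected — the log-ratio is
undefined on a zero background — with guidance to set the value manually.

Every window on the requested strands whose score is at least the element's
cutoff is reported as a hit; there is no best-per-sequence reduction and no
overlap suppression, because the downstream positional statistics are
defined over *all* detected instances. Antisense hits are scored against
the reverse complement and reported at the plus-strand coordinate of their
5′-most base (in the motif's own reading direction) with strand `-`.

### Coordinates

Positions are reported on the biology-style TSS axis: the TSS base is `+1`,
the base before it `-1`, and there is no position `0`. Each PWM carries an
`anchor_offset` marking its functional base (the `A+1` of an initiator, the
`C+1` of a TCT-type initiator), so hits report both their start and their
anchor-base position. Spacings of initiator-dependent elements are measured
on the same zero-free convention with the anchor's `A+1` as `+1`; a DPE
starting 27 bases downstream of the `A+1` is therefore at spacing `+28`.

### Numerical choices

- **Pseudocount.** Probabilities are regularized per column as
  `q = (P + c) / (1 + 4c)` with `c = 1e-3` (configurable) before taking
  log2, so zero cells stay finite while consensus rankings are essentially
  unchanged. With `c = 0`, a zero probability is an error.
- **Ambiguous bases.** `N` scores as the column minimum: an ambiguous base
  can suppress a hit but never create one. Other IUPAC ambiguity codes are
  degraded to `N` on input, with a warning. Soft-masked (lowercase) bases
  are ordinary bases by default; a flag converts them to `N`.
- **Scores** are printed to 3 decimals in hit tables; PWM files carry 6
  decimal digits and round-trip bit-exactly at that precision.

## The element library

The bundled library covers TATA, BREu, BREd, the human Inr, the
`BBCA_+1_BW` initiator, the Drosophila Inr (dInr), TCT and dTCT, DPE, MTE,
the MTE/DPE Bridge, the pause button (PB), Ohler Motif 1 and the GAGA
factor site. The shipped matrices are **synthetic reconstructions**: each
is built from the element's published IUPAC consensus with fixed per-letter
probability profiles (single base 0.85; two-fold degeneracy 0.45/0.45;
three-fold 0.30/0.30/0.30/0.10; `N` uniform). Experimentally fitted
matrices from existing motif resources are deliberately not redistributed;
users who need them can import any matrix in the documented PWM text format
as a user motif, which is scanned identically to built-ins.

### Default cutoffs

Cutoffs are not an intrinsic property of a PWM, and published tools rarely
state theirs. The defaults here are the **equal-error-rate operating
point** at GC 0.5: the score at which the miss rate on draws from the motif
model equals the per-window false-positive rate on the background. Both
error curves are computed exactly by per-column convolution of the score
distribution (positions are independent), on a 1e-3-bit grid, and the
cutoff is floored to one decimal. For sharply defined motifs this yields
error rates of a few percent; for intrinsically degenerate elements
(Inr-class, DPE) the balanced error is necessarily higher — these motifs
are weak signals by nature, which is precisely why their *positional*
distribution, not their mere presence, carries the QC information. An
earlier candidate policy (fixed 95% retention of motif draws) was rejected
because it produced per-window false-positive rates above 10% for
low-information matrices and let systematic overlap artifacts rival true
modal positions. Cutoffs are per-element configuration values and can be
overridden at scan time.

### Composite rules

Downstream elements function at strict spacings from an initiator. The
shipped rules call DPE at spacing +28..+33, MTE at +18..+22 and Bridge at
+18..+20 from a dInr anchor on the same sequence and strand. Each dependent
hit receives at most one call per rule: the highest-scoring in-window
anchor wins, ties resolve toward the spacing closest to the window midpoint
and then the smaller spacing. Dependent hits without a qualifying anchor
are kept and flagged *orphan* rather than suppressed, so their raw
positional distribution remains visible to the QC module. Anchoring the
human downstream elements to Inr, or changing windows, is a one-line edit
in `rules.yaml`.

## Positional QC statistic

For each element the hit list is reduced to a per-position table: number of
hits, fraction (%) of that element's hits at the position (fractions sum to
100 over occupied positions — the denominator is the element's total hit
count, the only reading under which per-element profiles normalize), and
the mean and median hit score. Independent elements are profiled by start
(or anchor-base) position on the TSS axis; initiator-dependent elements by
their spacing on the anchor-A+1 axis, computed from composite calls so that
orphans are excluded. Mean and median are both emitted because both
summaries are in circulation for this statistic; plots default to the mean.

Each distribution is summarized by its **modal position**, the modal
fraction, and a **concentration**: the fraction of hits within ±2 bases of
the mode, computed on the linearized axis so the window never gains a free
slot by straddling the missing zero. Modal ties resolve toward the position
nearest the hit-weighted mean of the axis (then the smaller position), so a
flat profile reports its central position rather than an arbitrary edge.
Comparing concentrations element-by-element across datasets ranks TSS
datasets by positional accuracy: elements with strict spacing requirements
pile up at their functional position only when the TSSs themselves are
mapped precisely.

## Synthetic promoter generator

The generator emulates exactly the structure the QC statistic measures:
fixed-width windows with i.i.d. background bases at a controlled GC
fraction, and element instances planted at specified positions. Each plant
has a per-sequence probability, a discrete symmetric positional jitter
(rounded normal draw, truncated at the sequence bounds), and either the
consensus instance (default) or an instance sampled column-wise from the
PWM. Dependent elements can be planted relative to a previously planted
anchor's A+1. Later plants overwrite earlier ones where they overlap; the
overwritten ground-truth row is marked. Ground truth is a separate table,
never encoded only in FASTA headers.

Two deliberate design points:

- **Consensus instances by default.** A consensus plant is an exact
  maximal-score match, so recovery experiments measure the scanning and
  composite machinery itself, not cutoff calibration. Experiments that
  should see realistic motif variability — notably the sharp-vs-jittered
  dataset comparison, where instance variability is part of what the
  concentration statistic must tolerate — set `sample_from_pwm=True`
  explicitly.
- **What the generator does not model:** dinucleotide composition,
  repeats, isochores, correlated element co-occurrence beyond a single
  anchor, or read-level noise of any TSS assay. Passing recovery tests on
  these fixtures demonstrates correctness of the detection and QC
  machinery, not performance on real genomic sequence.

## Problem sizes and reproducibility

The bundled experiments use 1,000 windows of ±100 bp for architecture
recovery (initiator at −2, DPE at +28), 500 windows for each per-element
modal-position run and for each arm of the jitter comparison (sd 0 vs
sd 5), 200 random sequences × 5 random matrices for the brute-force
cross-check, and 100 sequences for the strand-symmetry check. All
randomness flows from a single integer seed through NumPy generators; the
same seed gives byte-identical FASTA, ground truth and hit tables.

## Known limitations

- The synthetic matrices are consensus-derived; absolute scores and
  cutoffs are not comparable to tools shipping experimentally fitted
  matrices, although positional statistics behave the same way.
- The single-nucleotide background ignores dinucleotide bias (CpG
  depletion), which inflates background hit rates for CpG-containing
  motifs in real vertebrate sequence.
- Scores are compared to fixed cutoffs; no p-value calibration is
  performed.
- DCE-style multi-part elements are expressible only as independent
  user motifs; genome-scale scanning (indexing, chunking, parallelism) is
  out of scope.
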