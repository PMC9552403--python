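# Methods

This note documents the models and procedures implemented in `pigatlas`,
the parameters that matter, the numerical conventions, and what the
synthetic data does and does not establish.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open `[start, end)` (the BED
convention). GTF-like gene models and RepeatMasker `.out` records, which
are 1-based inclusive on disk, are converted on read; variant positions
are accepted 1-based (as GWAS tables report them) and converted
internally. A single convention removes the classic off-by-one family of
bugs; every boundary below is tested at its exact value.

Merging uses a sort-and-sweep with `gap = 0` by default, so book-ended
intervals merge — the behaviour of `bedtools merge`, which is the
standard tool for this step. Chromosome names are opaque strings; a
total naming mismatch between two inputs produces a warning listing the
names private to each side rather than silent zero overlap.

## Peak atlas and intensity

`build_atlas` supports three views of the per-sample peak calls:

* **union** — merge everything (the full regulatory repository);
* **reproducible** — within each tissue, merge the union of the
  replicates' peaks and keep only merged segments overlapped by at least
  one peak from *every* replicate; then merge survivors across tissues.
  This is the high-confidence atlas used downstream by default.
* **min_samples(k)** — union segments supported by ≥ k distinct samples.

Peak intensity is **PPKM**: `count / (length/1e3) / (colsum/1e6)`, with
`colsum` the sample's total reads *in peaks*. The denominator choice
matters: using in-peak totals makes the statistic self-contained (counts
per merged peak are the only input) and gives the exact column identity
`Σ ppkm·len_kb = 1e6`, which the tests verify to 1e-6 relative. Using
all mapped reads instead would only rescale columns by the sample's FRIP
and cancels from every ratio-based rule downstream. PPKM is invariant to
library depth by construction.

Sample clustering uses Ward linkage on Euclidean distances of
log₂(x + 1)-transformed columns. The log transform is a deliberate
choice: raw PPKM distances are dominated by a handful of very intense
peaks, while tissue identity is carried by relative intensity across
many peaks. An optional `top_n` restricts to the most variable rows
(the "top peaks / top variable genes" convention for atlas dendrograms).

Peak genomic category is assigned by the peak **center** with precedence
CDS > 5′UTR > 3′UTR > intron > intergenic; a center inside a gene span
but in no classified exonic feature is intronic. Center-based assignment
makes the five categories a true partition even for peaks straddling
features. Proximal/distal uses the distance from peak center to the
nearest same-chromosome TSS, inclusive at 1000 bp.

## Specificity rules

A feature is **tissue-specific** when its replicate-mean intensity in
one tissue is positive and ≥ 2-fold the maximum mean over every other
tissue, *inclusive* at the boundary ("at least twice"). With any
threshold > 1 the call is unique per feature: mutual two-fold dominance
forces both means to zero, which the positivity condition excludes; the
implementation asserts this on every run. The rule is scale-invariant
and monotone in the threshold (both property-tested). Tissues where the
feature is absent still count toward the background maximum.

**System-specific** calls apply the same rule to unweighted means of the
member tissues' means. **Ubiquitous** ("conserved") peaks are atlas
peaks overlapping (≥ 1 bp) the called peak set of at least
`ceil(0.9 × n_tissues)` tissues — presence is a peak-call notion, not an
intensity threshold, because a region can be called open at modest
intensity everywhere.

## Peak–gene link map

Candidate pairs are peak–gene combinations on one chromosome with
|TSS − peak center| ≤ 500 kb (inclusive), the standard cis window within
which most promoter-anchored chromatin interactions fall. Each pair is
scored with Spearman's ρ (average ranks for ties) and a two-sided p-value
from the t approximation on n − 2 degrees of freedom; |ρ| = 1 maps to
p = 0, and an exact permutation p is available for n ≤ 8 where the
approximation is poor. Pairs with a constant vector, or fewer than 5
complete observations, are excluded from testing *and* from the BH
denominator (reported as "degenerate").

Benjamini–Hochberg is applied **once across all tested pairs** — one
q-value threshold over the whole map, not per peak or per chromosome —
and significance is strict (`q < alpha`). Signed distance is
TSS − center, negated for minus-strand genes, so positive always means
the peak lies 5′ of the gene.

Sign profiles label each peak by the signs of its significant links
(positive-only / negative-only / mixed). Because "fraction of
correlations that are positive-only" can be tallied over peaks or over
associations (each association inheriting its peak's label), both
tallies are computed and reported.

## TE accessibility and permutation testing

The accessibility criterion is reciprocal coverage: an overlap qualifies
when it covers ≥ 50% of the TE *and* ≥ 20% of the peak, both inclusive.
The two arms are asymmetric by design — a short TE buried in a long peak
fails the peak arm — and a test guards against accidentally symmetric
implementations. Per tissue, the best peak is the one with the largest
qualifying overlap (ties to the leftmost). Sharing classes are
single-tissue, all-tissues, or intermediate(k), which partition the
accessible set.

Spatial enrichment uses a deliberately transparent permutation scheme:
every query interval is re-placed uniformly at random on its own
chromosome, preserving its length and chromosome assignment (overlaps
among placed intervals permitted), and the statistic — count of query
intervals touching the reference, or the Jaccard of covered bases — is
recomputed. Empirical one-sided p-values use the +1 correction,
`p = (1 + #{null as-or-more-extreme}) / (1 + n_perm)`, so p is never 0
and never below `1/(n_perm+1)`; with the default 100 permutations the
floor is 1/101 ≈ 0.0099. The count statistic is integer-valued and tied
at small problem sizes, which makes its p-values conservative
(super-uniform); the Jaccard statistic is effectively continuous and is
the right choice when calibration matters. This single scheme replaces a
suite of spatial-correlation statistics; it reproduces enrichment or
depletion verdicts, not any specific published statistic.

Variant enrichment reuses the same machinery with variants as 1-bp query
intervals and the count statistic, whose observed value equals the
in-peak count from the annotator by construction (tested).

## Synthetic data: what it emulates

Defaults (all in `SimulationConfig`): 4 tissues × 2 replicates,
2 chromosomes × 10 Mb, 2000 peaks (width 300–700 bp), 500 single-exon
genes (2–5 kb), in-peak depth 2×10⁶ reads/sample, negative-binomial
dispersion 0.2, seed-driven PCG64 throughout (each stage draws from its
own `(stage, seed)` stream, so stages are independently reproducible and
byte-identical across runs).

Planted structure:

* 20% of peaks are tissue-specific — open only in their target tissue at
  `specific_fold = 4` times baseline, with a 2% residual background
  elsewhere. A tissue-specific regulatory element is *closed*, not
  merely weaker, in other tissues; this matches both the biology and the
  fraction of specific peaks a multi-tissue atlas reports (roughly a
  fifth of the reproducible atlas).
* 5% are ubiquitous (open everywhere at baseline).
* The remainder are broadly shared: each tissue present with probability
  0.97, resampled to guarantee ≥ 2 present tissues. Breadth here is a
  calibrated choice, not an accident: with NB dispersion 0.2 the
  replicate-mean of a flat peak has ≈ 32% relative noise, and a flat
  peak seen in only k of 4 tissues falsely crosses the inclusive 2-fold
  rule with probability ≈ 13% (k = 2), 4% (k = 3), 1.8% (k = 4). A
  generator with many narrowly-shared flat peaks would therefore make
  the fold rule look arbitrarily bad regardless of implementation; the
  chosen mix yields expected precision ≈ 0.92 at recall ≈ 1.0, which is
  what the rule genuinely delivers under these noise conditions.
* Per-sample peak calls ("BED files") are counts thresholded at an
  absolute detection floor (100 reads), so replicate-reproducibility
  filtering is exercised with realistic dropout of weak peaks. This is
  why recovery of the planted ubiquitous set tops out around 0.8: a
  low-baseline peak occasionally misses the floor in one replicate of
  one tissue, and the 90% rule on 4 tissues demands presence in all 4.
* Expression: linked genes follow
  `baseline + s · effect · log1p(ppkm) + N(0, noise_sd)` against the
  *realized* peak intensity of one nearby peak (|TSS − center| ≤ 500 kb,
  distinct genes and peaks per link), with sign s = −1 for a configurable
  fraction; other genes are independent noise. Everything is then
  TPM-normalized. With 60 samples and effect 3 the planted links are
  recovered exactly with correct signs; with 8 samples they are not
  individually significant after global BH — a faithful reflection of
  why atlas studies pool samples for correlation mapping.
* TEs: one subset overlaps a called peak by *exactly* the binding arm of
  the 50%/20% criterion (just-passing), an equal subset by one base less
  (just-failing, and placed so no other peak can rescue it); the rest
  are uniform. Class labels are drawn at the SINE/LINE/LTR/DNA
  proportions typical of accessible TEs (40/30/23/7%).
* Variants: exact counts inside and outside peak spans.

Not emulated: read-level artefacts (GC, mappability, duplicates), peak
calling itself, multi-exon gene structure (so the intron category never
occurs in synthetic data and is tested on constructed fixtures),
LD between variants, inter-individual genotype effects, and any sequence
content. Passing tests therefore demonstrate correctness of the
*downstream* computations and honest behaviour of the statistical rules
under controlled noise — not performance on real libraries.

## Numerical and design choices

* "At least 10% of samples" support filters use a ceiling on the count;
  "more than 2 samples" is a strict inequality; expression comparisons
  (TPM > threshold) are strict. All three boundaries are tested.
* Fold = ∞ is allowed when the background maximum is zero (and reported
  as such); all-zero features are never specific.
* BH is the textbook step-up (`q_(i) = min_{j≥i} min(1, p_(j)·m/j)`),
  cross-checked against an independent implementation on random vectors.
* Ties in nearest-gene and effector-gene ranking break deterministically
  (distance, then gene id; q, then |ρ|, then gene id), making outputs
  permutation-stable.
* Nearest-gene assignment is within-chromosome only; peaks on a
  chromosome without genes are left unassigned rather than matched
  across chromosomes.
* The pipeline writes `run_report.json` with sorted keys and keeps wall
  times in the log only, so identical configurations produce
  byte-identical reports.
* Problem sizes in the tests and drivers (2000 peaks, 300-peak /
  60-sample link studies, 100–200 permutation datasets) are chosen so the
  full suite exercises every stage end to end in well under a minute
  each while keeping the statistical checks well-powered.

## Known limitations

* The reproducible-mode atlas requires overlap by *every* replicate of a
  tissue; tissues with many replicates would be penalized relative to a
  "≥ 2 replicates" rule (not distinguishable at 2 replicates/tissue).
* The permutation null treats query intervals as independent, ignoring
  clustering along the genome; observed enrichment against a clustered
  reference is therefore anti-conservative in the same way the simple
  shuffle null always is.
* The t approximation for Spearman p-values is inaccurate below ~10
  samples; the exact option exists but is factorial-time.
* PPKM inherits the compositional caveat of all within-sample
  normalizations: a tissue whose accessibility is globally elevated
  shifts every other peak's PPKM down slightly.
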