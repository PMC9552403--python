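# pigatlas

Downstream analysis of a multi-tissue ATAC-seq chromatin-accessibility
atlas, of the kind built for livestock functional-annotation studies (the
motivating design: 20 pig tissues, two biological replicates each, with
matched RNA-seq). The package takes per-sample peak calls and in-peak
read counts and carries them through to regulatory interpretation:

* **Peak atlas** — merge per-sample peaks into non-redundant regions,
  optionally keeping only peaks evidenced in every biological replicate
  of a tissue; normalize intensity as **PPKM** (peaks per kilobase per
  million: count / (length/10³) / (in-peak depth/10⁶)); cluster samples
  by Ward linkage on log₂(PPKM + 1); split peaks into TSS-proximal
  (≤ 1 kb) and distal; annotate peak centers as CDS / 5′UTR / 3′UTR /
  intron / intergenic.
* **Tissue specificity** — a peak (or gene, on TPM) is specific to a
  tissue when its replicate-mean intensity there is at least **2-fold**
  the maximum over all other tissues (inclusive); the same rule applies
  across organ systems on unweighted system means. Peaks present in the
  called sets of at least **90%** of tissues are ubiquitously accessible.
* **Peak–gene links** — for every gene whose TSS lies within **500 kb**
  of a peak center, Spearman's ρ between PPKM and TPM across samples,
  with a two-sided p from t = ρ·√((n−2)/(1−ρ²)); Benjamini–Hochberg
  applied once across all pairs; links significant at **q < 0.01**.
  Per-peak sign profiles (positive-only / negative-only / mixed) and
  genes-per-peak / peaks-per-gene summaries by sign.
* **Transposable elements** — a TE is accessible in a tissue when a
  called peak overlaps it by ≥ 50% of the TE **and** ≥ 20% of the peak;
  sharing classes (single-tissue, all-tissue, intermediate), class
  composition (SINE/LINE/LTR/DNA), and a length-preserving uniform-shuffle
  permutation test for spatial enrichment or depletion of TEs in open
  chromatin.
* **Trait variants** — GWAS variants are intersected with the atlas;
  in-peak variants inherit the significant links of their host peak as
  ranked candidate effector genes, and a permutation test quantifies the
  in-peak excess.

A first-class synthetic-data generator (`pigatlas.simulate`) produces a
complete desk-scale study — replicate structure, negative-binomial
counts, planted tissue-specific / ubiquitous peaks, cis-coupled genes
with positive and negative effects, TEs placed to just-pass or just-fail
the accessibility criterion, and in/out-of-peak variants — with the
planted truth recorded, so every stage is testable without any download.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic atlas (4 tissues × 2 replicates, 2 chromosomes × 10 Mb,
2000 peaks, 500 genes, seed 1) and write their tables under `results/`:

```bash
$ python analysis/03_specificity.py --seed 1
tissue-specific peaks: 430 {'tissue2': 101, 'tissue4': 106, 'tissue3': 113, 'tissue1': 110}
planted recovery: precision 0.928, recall 0.998
system-specific peaks: 522
ubiquitous peaks: 1178 (recovers 80/100 planted)
```

430 peaks pass the inclusive 2-fold rule; 399 of them are planted
tissue-specific peaks assigned to the correct tissue (precision 0.928)
and only 1 of the 400 planted peaks is missed (recall 0.998). The
remaining calls are broadly shared peaks that cross the 2-fold boundary
by replicate noise — the price of a ratio rule at dispersion 0.2.

```bash
$ python analysis/04_link_map.py --seed 1
tested 2935 pairs (0 degenerate), 40 significant
planted links recovered: 40/40, sign correct 40/40
association-level sign fractions: {'positive_only': 0.7, 'negative_only': 0.3, 'mixed': 0.0}
global null: 0/2935 significant (0.0000 at alpha 0.01)
```

With 60 samples the link map recovers every planted peak–gene coupling
with its correct sign and reports nothing under a global null.

The whole pipeline can also be driven through one call with a single
hierarchical config (all thresholds exposed, defaults as above):

```python
from pigatlas import run_pipeline
report = run_pipeline({"seed": 1}, "out/")   # or a YAML path
```

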