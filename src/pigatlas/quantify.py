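"""Peak atlas construction, intensity normalization and sample-level QC.

The atlas is built by merging per-sample peak calls. Three modes are
supported:

* ``union`` — merge every sample's peaks into non-redundant segments (the
  "all merged peaks" view of the atlas);
* ``reproducible`` — within each tissue, keep only merged segments backed
  by every biological replicate of that tissue, then merge the survivors
  across tissues (the high-confidence view);
* ``min_samples`` — keep union segments supported by at least ``k``
  distinct samples.

Peak intensity is measured as PPKM (peaks per kilobase per million):
read count in the peak divided by peak length in kb and by the sample's
total in-peak reads in millions. Gene expression uses standard TPM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    build_trees,
    find_overlaps,
    merge_intervals,
)

VALID_KINDS = ("counts", "ppkm", "tpm")


@dataclass
class SampleSheet:
    """Maps matrix columns to samples and samples to tissues/replicates."""

    frame: pd.DataFrame  # columns: sample_id, tissue, replicate, [library_size]

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        pairs = self.frame[["tissue", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ValueError("duplicate (tissue, replicate) pair in sample sheet")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "SampleSheet":
        return cls(pd.DataFrame(records, columns=["sample_id", "tissue", "replicate"]))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.frame["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def tissue_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id, "tissue"]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id}")
        return str(row.iloc[0])

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.frame.loc[self.frame["tissue"] == tissue, "sample_id"])


@dataclass
class IntensityMatrix:
    """Feature-by-sample matrix tagged with its normalization state."""

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.df.index.duplicated().any():
            raise ValueError("duplicate row ids")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate column ids")
        if (self.df.to_numpy() < 0).any():
            raise ValueError("negative entries in intensity matrix")

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    def subset_rows(self, ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.df.loc[list(ids)], self.kind)


@dataclass
class PeakAtlas:
    """Merged peak atlas plus per-tissue call sets and per-peak support."""

    peaks: list[Peak]
    per_tissue_peaks: dict[str, list[Peak]]
    support: dict[str, set[str]]  # atlas peak id -> supporting sample ids
    counts: IntensityMatrix | None = None
    ppkm: IntensityMatrix | None = None

    @property
    def peak_ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def peak_lengths(self) -> dict[str, int]:
        return {p.id: p.length for p in self.peaks}

    def peak_by_id(self) -> dict[str, Peak]:
        return {p.id: p for p in self.peaks}

    def attach_counts(self, counts: IntensityMatrix) -> None:
        """Attach a counts matrix (subset to atlas peaks) and derive PPKM."""
        if counts.kind != "counts":
            raise ValueError("attach_counts expects kind='counts'")
        present = [pid for pid in self.peak_ids if pid in counts.df.index]
        missing = len(self.peaks) - len(present)
        if missing:
            raise ValueError(f"{missing} atlas peaks missing from counts matrix")
        self.counts = counts.subset_rows(self.peak_ids)
        self.ppkm = ppkm_normalize(self.counts, self.peak_lengths())


def _segments_with_support(
    per_sample_peaks: Mapping[str, Sequence[Peak]],
) -> tuple[list[GenomicInterval], dict[int, set[str]]]:
    """Union-merge all samples' peaks; record which samples touch each segment."""
    all_ivs = [p.interval for peaks in per_sample_peaks.values() for p in peaks]
    merged = merge_intervals(all_ivs)
    trees = build_trees(merged)
    support: dict[int, set[str]] = {i: set() for i in range(len(merged))}
    for sample_id, peaks in per_sample_peaks.items():
        for p in peaks:
            tree = trees.get(p.chrom)
            if tree is None:
                continue
            for node in tree.overlap(p.start, p.end):
                support[node.data].add(sample_id)
    return merged, support


def _tissue_merged(
    per_sample_peaks: Mapping[str, Sequence[Peak]], sheet: SampleSheet, tissue: str
) -> tuple[list[GenomicInterval], dict[int, set[str]]]:
    subset = {s: per_sample_peaks.get(s, []) for s in sheet.samples_of(tissue)}
    return _segments_with_support(subset)


def build_atlas(
    per_sample_peaks: Mapping[str, Sequence[Peak]],
    sheet: SampleSheet,
    mode: str = "union",
    min_samples: int | None = None,
) -> PeakAtlas:
    """Merge per-sample peak calls into a non-redundant atlas.

    In ``reproducible`` mode the per-tissue call sets are themselves the
    replicate-backed sets; in the other modes they are plain within-tissue
    merges. Per-peak support (overlapping sample ids) is recorded for every
    atlas peak.
    """
    if mode not in ("union", "reproducible", "min_samples"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "min_samples":
        if min_samples is None or min_samples < 1:
            raise ValueError("min_samples mode requires k >= 1")
    unknown = set(per_sample_peaks) - set(sheet.sample_ids)
    if unknown:
        raise ValueError(f"samples not in sheet: {sorted(unknown)}")

    per_tissue: dict[str, list[Peak]] = {}
    reproducible_per_tissue: dict[str, list[GenomicInterval]] = {}
    for tissue in sheet.tissues:
        merged, support = _tissue_merged(per_sample_peaks, sheet, tissue)
        replicates = set(sheet.samples_of(tissue))
        kept = [iv for i, iv in enumerate(merged) if support[i] >= replicates]
        reproducible_per_tissue[tissue] = kept
        source = kept if mode == "reproducible" else merged
        per_tissue[tissue] = [
            Peak.from_coords(iv.chrom, iv.start, iv.end) for iv in source
        ]

    if mode == "reproducible":
        atlas_ivs = merge_intervals(
            [iv for ivs in reproducible_per_tissue.values() for iv in ivs]
        )
    else:
        union_ivs, union_support = _segments_with_support(per_sample_peaks)
        if mode == "union":
            atlas_ivs = union_ivs
        else:  # min_samples
            atlas_ivs = [
                iv
                for i, iv in enumerate(union_ivs)
                if len(union_support[i]) >= int(min_samples)  # type: ignore[arg-type]
            ]

    peaks = [Peak.from_coords(iv.chrom, iv.start, iv.end) for iv in atlas_ivs]
    support_sets: dict[str, set[str]] = {p.id: set() for p in peaks}
    hits = find_overlaps(
        atlas_ivs, [p.interval for ps in per_sample_peaks.values() for p in ps]
    )
    flat_samples = [
        sample_id for sample_id, ps in per_sample_peaks.items() for _ in ps
    ]
    for qi, si, _ in hits:
        support_sets[peaks[qi].id].add(flat_samples[si])
    return PeakAtlas(peaks=peaks, per_tissue_peaks=per_tissue, support=support_sets)


# ---------------------------------------------------------------------------
# normalization


def ppkm_normalize(
    counts: IntensityMatrix, peak_lengths: Mapping[str, int]
) -> IntensityMatrix:
    """Peaks-per-kilobase-per-million normalization of in-peak read counts.

    ppkm[i, j] = count[i, j] / ((length_i / 1e3) * (colsum_j / 1e6)) where
    colsum_j is sample j's total in-peak reads, so for every sample
    sum_i ppkm[i, j] * length_i / 1e3 == 1e6. Invariant to per-sample
    library depth.
    """
    if counts.kind != "counts":
        raise ValueError("ppkm_normalize expects a counts matrix")
    lengths = np.array([peak_lengths[pid] for pid in counts.row_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("peak lengths must be positive")
    values = counts.df.to_numpy(dtype=float)
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = [counts.col_ids[i] for i in zero]
        raise ValueError(f"all-zero count column(s): {bad}")
    ppkm = values / (lengths[:, None] / 1e3) / (colsums[None, :] / 1e6)
    return IntensityMatrix(
        pd.DataFrame(ppkm, index=counts.df.index, columns=counts.df.columns), "ppkm"
    )


def tpm_normalize(
    counts: IntensityMatrix, gene_lengths: Mapping[str, int]
) -> IntensityMatrix:
    """Standard TPM: length-normalized rates scaled to 1e6 per column."""
    if counts.kind != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    lengths = np.array([gene_lengths[g] for g in counts.row_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.df.to_numpy(dtype=float) / lengths[:, None]
    colsums = rates.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = [counts.col_ids[i] for i in zero]
        raise ValueError(f"all-zero count column(s): {bad}")
    tpm = 1e6 * rates / colsums[None, :]
    return IntensityMatrix(
        pd.DataFrame(tpm, index=counts.df.index, columns=counts.df.columns), "tpm"
    )


def filter_expressed(
    tpm: IntensityMatrix,
    min_tpm: float,
    min_support: float | int,
    strict_support: bool = False,
) -> list[str]:
    """Retain genes expressed above ``min_tpm`` in enough samples.

    ``min_support`` is either an absolute sample count or a fraction in
    (0, 1] (converted with a ceiling, so "at least 10% of 71" means >= 8).
    With ``strict_support`` the count must strictly exceed the threshold
    ("in more than 2 samples"); otherwise at-least is used. The expression
    comparison itself is always strict (TPM > min_tpm).
    """
    n = len(tpm.col_ids)
    counts = (tpm.df.to_numpy() > min_tpm).sum(axis=1)
    if isinstance(min_support, float) and 0 < min_support <= 1:
        threshold = math.ceil(min_support * n)
        if strict_support:
            raise ValueError("strict_support applies to absolute counts only")
        keep = counts >= threshold
    else:
        threshold = int(min_support)
        if threshold < 1:
            raise ValueError("absolute min_support must be >= 1")
        keep = counts > threshold if strict_support else counts >= threshold
    return [g for g, k in zip(tpm.row_ids, keep) if k]


# ---------------------------------------------------------------------------
# peak annotation


def _tss_arrays(genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def distance_to_nearest_tss(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> dict[str, int | None]:
    """Unsigned bp distance from each peak center to the nearest same-chrom TSS."""
    if not genes:
        raise ValueError("need at least one gene model")
    tss = _tss_arrays(genes)
    out: dict[str, int | None] = {}
    for p in peaks:
        arr = tss.get(p.chrom)
        if arr is None:
            out[p.id] = None
            continue
        i = int(np.searchsorted(arr, p.center))
        best = None
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                d = abs(int(arr[j]) - p.center)
                best = d if best is None else min(best, d)
        out[p.id] = best
    return out


def classify_proximal_distal(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], threshold: int = 1000
) -> dict[str, str]:
    """Partition peaks into promoter-like (center within ``threshold`` bp of
    a TSS, inclusive) and enhancer-like distal peaks."""
    dist = distance_to_nearest_tss(peaks, genes)
    return {
        pid: "proximal" if d is not None and d <= threshold else "distal"
        for pid, d in dist.items()
    }


CATEGORIES = ("CDS", "UTR5", "UTR3", "intron", "intergenic")


def annotate_genomic_category(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> tuple[dict[str, str], dict[str, float]]:
    """Assign each peak center a genomic category with precedence
    CDS > UTR5 > UTR3 > intron > intergenic.

    ``intron`` means the center lies inside a gene span but in none of its
    classified exonic features. Returns per-peak labels and the category
    fractions (which sum to 1 over the five categories).
    """
    feature_ivs: dict[str, list[GenomicInterval]] = {"CDS": [], "UTR5": [], "UTR3": []}
    for g in genes:
        for cat, iv in g.features:
            if cat in feature_ivs:
                feature_ivs[cat].append(iv)
    gene_spans = [g.span for g in genes]
    trees = {cat: build_trees(ivs) for cat, ivs in feature_ivs.items()}
    span_trees = build_trees(gene_spans)

    def center_in(trees_for_cat: dict, chrom: str, pos: int) -> bool:
        tree = trees_for_cat.get(chrom)
        return tree is not None and bool(tree.overlap(pos, pos + 1))

    labels: dict[str, str] = {}
    for p in peaks:
        c = p.center
        for cat in ("CDS", "UTR5", "UTR3"):
            if center_in(trees[cat], p.chrom, c):
                labels[p.id] = cat
                break
        else:
            labels[p.id] = "intron" if center_in(span_trees, p.chrom, c) else "intergenic"
    n = max(len(peaks), 1)
    fractions = {cat: sum(1 for v in labels.values() if v == cat) / n for cat in CATEGORIES}
    return labels, fractions


def frip(
    in_peak_counts: Mapping[str, float], total_reads: Mapping[str, float]
) -> dict[str, float]:
    """Fraction of reads in peaks per sample (library quality statistic)."""
    out = {}
    for sample, total in total_reads.items():
        in_peak = in_peak_counts.get(sample, 0.0)
        if total < in_peak:
            raise ValueError(f"sample {sample}: total reads {total} < in-peak {in_peak}")
        out[sample] = in_peak / total if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# sample clustering


def _tree_to_newick(node: hierarchy.ClusterNode, labels: Sequence[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _tree_to_newick(node.left, labels, node.dist)
    right = _tree_to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_samples(
    intensity: IntensityMatrix,
    top_n: int | None = None,
    log_transform: bool = True,
) -> str:
    """Ward-linkage hierarchical clustering of samples.

    Columns are log2(x + 1)-transformed (tissue identity is carried by
    relative, not absolute, intensity; untransformed values let a handful
    of huge peaks dominate the Euclidean metric) and clustered with Ward's
    method. ``top_n`` restricts to the most variable rows first. Returns a
    newick string with branch lengths, leaves labelled by sample id.
    """
    if len(intensity.col_ids) < 2:
        raise ValueError("clustering needs at least 2 samples")
    values = intensity.df.to_numpy(dtype=float)
    if top_n is not None and top_n < values.shape[0]:
        variances = values.var(axis=1)
        order = np.argsort(-variances, kind="stable")[:top_n]
        values = values[np.sort(order)]
    if log_transform:
        values = np.log2(values + 1.0)
    linkage = hierarchy.linkage(values.T, method="ward")
    root = hierarchy.to_tree(linkage)
    return _tree_to_newick(root, intensity.col_ids, root.dist) + ";"
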