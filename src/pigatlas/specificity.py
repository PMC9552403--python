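"""Tissue-specific, system-specific and ubiquitously accessible calls.

The fold rule: a feature is specific to tissue *t* when its replicate-mean
intensity there is positive and at least ``fold_threshold`` times the
maximum mean over every other tissue (inclusive at the boundary, so a
feature at exactly twice the runner-up is called). With any threshold > 1
the call is provably unique per feature: two tissues can only dominate
each other two-fold if both means are zero, which the positivity condition
excludes.

"Conserved" (ubiquitously accessible) peaks are atlas peaks present in the
called peak sets of at least 90% of tissues — presence is a peak-call
notion (>= 1 bp overlap with a tissue's called set), not an intensity
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, Peak, build_trees
from .quantify import IntensityMatrix, SampleSheet


@dataclass(frozen=True)
class SpecificityCall:
    feature_id: str
    level: str  # "tissue" or "system"
    label: str
    fold: float  # achieved target_mean / max_other_mean; inf when denominator 0
    target_mean: float


@dataclass(frozen=True)
class ConservedCall:
    feature_id: str
    n_present: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_present / self.n_total


def tissue_means(matrix: IntensityMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Arithmetic mean over each tissue's replicate columns.

    Returns a feature x tissue DataFrame (tissues in sheet order).
    """
    cols = set(matrix.col_ids)
    data = {}
    for tissue in sheet.tissues:
        samples = [s for s in sheet.samples_of(tissue) if s in cols]
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no columns in the matrix")
        data[tissue] = matrix.df[samples].mean(axis=1)
    unmapped = cols - set(sheet.sample_ids)
    if unmapped:
        raise ValueError(f"columns not mapped to any tissue: {sorted(unmapped)}")
    return pd.DataFrame(data, index=matrix.df.index)


def _call_from_means(
    means: pd.DataFrame, fold_threshold: float, level: str
) -> list[SpecificityCall]:
    if means.shape[1] < 2:
        raise ValueError("need at least 2 groups to call specificity")
    values = means.to_numpy(dtype=float)
    labels = list(means.columns)
    order = np.argsort(-values, axis=1, kind="stable")
    rows = np.arange(values.shape[0])
    top_idx = order[:, 0]
    top = values[rows, top_idx]
    second = values[rows, order[:, 1]]
    with np.errstate(divide="ignore"):
        fold = np.where(second > 0, top / np.where(second > 0, second, 1.0), np.inf)
    called = (top > 0) & (fold >= fold_threshold)
    calls = [
        SpecificityCall(
            feature_id=str(means.index[i]),
            level=level,
            label=labels[top_idx[i]],
            fold=float(fold[i]),
            target_mean=float(top[i]),
        )
        for i in np.flatnonzero(called)
    ]
    if fold_threshold > 1:
        assert len({c.feature_id for c in calls}) == len(calls), (
            "uniqueness theorem violated: a feature was called specific twice"
        )
    return calls


def call_specific(
    means: pd.DataFrame, fold_threshold: float = 2.0
) -> list[SpecificityCall]:
    """Call tissue-specific features from a feature x tissue mean matrix."""
    return _call_from_means(means, fold_threshold, level="tissue")


def call_group_specific(
    means: pd.DataFrame,
    grouping: Mapping[str, str],
    fold_threshold: float = 2.0,
) -> list[SpecificityCall]:
    """Call system-specific features; the system mean is the unweighted mean
    of its member tissues' means, and the same inclusive fold rule applies
    across systems."""
    missing = set(means.columns) - set(grouping)
    if missing:
        raise ValueError(f"tissues without a system: {sorted(missing)}")
    systems: dict[str, list[str]] = {}
    for tissue in means.columns:
        systems.setdefault(grouping[tissue], []).append(tissue)
    if len(systems) < 2:
        raise ValueError("need at least 2 systems")
    sys_means = pd.DataFrame(
        {sys: means[members].mean(axis=1) for sys, members in systems.items()},
        index=means.index,
    )
    return _call_from_means(sys_means, fold_threshold, level="system")


def call_conserved(
    per_tissue_peaks: Mapping[str, Sequence[Peak]],
    atlas_peaks: Sequence[Peak],
    min_fraction: float = 0.9,
) -> list[ConservedCall]:
    """Atlas peaks present (>=1 bp overlap with a called peak) in at least
    ``ceil(min_fraction * n_tissues)`` tissues."""
    tissues = list(per_tissue_peaks)
    if not tissues:
        raise ValueError("need at least one tissue")
    n_total = len(tissues)
    need = math.ceil(min_fraction * n_total)
    presence = np.zeros(len(atlas_peaks), dtype=int)
    for tissue in tissues:
        trees = build_trees([p.interval for p in per_tissue_peaks[tissue]])
        for i, peak in enumerate(atlas_peaks):
            tree = trees.get(peak.chrom)
            if tree is not None and tree.overlap(peak.start, peak.end):
                presence[i] += 1
    return [
        ConservedCall(feature_id=atlas_peaks[i].id, n_present=int(presence[i]), n_total=n_total)
        for i in np.flatnonzero(presence >= need)
    ]


def nearest_gene(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> dict[str, tuple[str, int]]:
    """Nearest gene by |TSS - peak center| on the same chromosome.

    Ties go to the lexicographically smaller gene id. Peaks on a
    chromosome without genes are omitted from the result.
    """
    if not genes:
        raise ValueError("need at least one gene model")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.id))
    arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arrays[chrom] = (np.array([t for t, _ in pairs]), [gid for _, gid in pairs])
    out: dict[str, tuple[str, int]] = {}
    for p in peaks:
        entry = arrays.get(p.chrom)
        if entry is None:
            continue
        tss_arr, ids = entry
        i = int(np.searchsorted(tss_arr, p.center))
        best: tuple[int, str] | None = None
        # examine the flanking TSS positions plus any ties at equal distance
        candidates = set()
        for j in (i - 1, i):
            if 0 <= j < tss_arr.size:
                candidates.add(j)
        if candidates:
            dmin = min(abs(int(tss_arr[j]) - p.center) for j in candidates)
            lo = np.searchsorted(tss_arr, p.center - dmin, side="left")
            hi = np.searchsorted(tss_arr, p.center + dmin, side="right")
            for j in range(int(lo), int(hi)):
                d = abs(int(tss_arr[j]) - p.center)
                cand = (d, ids[j])
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out[p.id] = (best[1], best[0])
    return out
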