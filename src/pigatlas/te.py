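"""Chromatin accessibility of transposable elements.

A TE is accessible in a tissue when some called peak of that tissue
overlaps it by at least 50% of the TE length AND at least 20% of the peak
length (both inclusive). The two arms are deliberately asymmetric: a short
TE buried in a long peak fails the peak arm, and a peak clipping the edge
of a long TE fails the TE arm.

Spatial enrichment or depletion of TEs in open chromatin is assessed with
a transparent permutation test: each query interval is re-placed uniformly
at random on its own chromosome, preserving its length, and the overlap
statistic is recomputed; empirical one-sided p-values use the +1
correction so p is never 0 and never below 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    Peak,
    TEAnnotation,
    TE_CLASSES,
    build_trees,
    merge_intervals,
)


@dataclass
class AccessibleTE:
    """A TE meeting the 50%/20% criterion in at least one tissue."""

    te: TEAnnotation
    tissues: set[str] = field(default_factory=set)
    best_peak: dict[str, str] = field(default_factory=dict)  # tissue -> peak id

    @property
    def id(self) -> str:
        return self.te.id

    def sharing(self, n_total_tissues: int) -> str:
        k = len(self.tissues)
        if k == 1:
            return "tissue_specific"
        if k == n_total_tissues:
            return "shared_all"
        return f"intermediate({k})"


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: tuple[float, ...]
    p_enrich: float
    p_deplete: float

    @property
    def direction(self) -> str:
        if self.p_enrich < self.p_deplete:
            return "enriched"
        if self.p_deplete < self.p_enrich:
            return "depleted"
        return "neutral"


def call_accessible_tes(
    tes: Sequence[TEAnnotation],
    per_tissue_peaks: Mapping[str, Sequence[Peak]],
    te_fraction: float = 0.5,
    peak_fraction: float = 0.2,
) -> list[AccessibleTE]:
    """Apply the reciprocal-coverage criterion per tissue.

    overlap >= te_fraction * len(TE) and overlap >= peak_fraction *
    len(peak), both inclusive. ``best_peak`` per tissue is the peak with
    the largest qualifying overlap, ties to the leftmost peak.
    """
    if not (0 < te_fraction <= 1) or not (0 < peak_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    out: dict[str, AccessibleTE] = {}
    for tissue, peaks in per_tissue_peaks.items():
        trees = build_trees([p.interval for p in peaks])
        for te in tes:
            tree = trees.get(te.interval.chrom)
            if tree is None:
                continue
            best: tuple[int, int, str] | None = None  # (-overlap, start, peak_id)
            for node in tree.overlap(te.interval.start, te.interval.end):
                peak = peaks[node.data]
                o = min(te.interval.end, peak.end) - max(te.interval.start, peak.start)
                if o >= te_fraction * te.length and o >= peak_fraction * peak.length:
                    cand = (-o, peak.start, peak.id)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                acc = out.setdefault(te.id, AccessibleTE(te=te))
                acc.tissues.add(tissue)
                acc.best_peak[tissue] = best[2]
    return [out[k] for k in sorted(out)]


def classify_sharing(
    accessible: Sequence[AccessibleTE], all_tissues: Sequence[str]
) -> dict[str, int]:
    """Counts of accessible TEs per sharing class (tissue_specific /
    shared_all / intermediate(k)); the classes partition the set."""
    n_total = len(all_tissues)
    for acc in accessible:
        extra = acc.tissues - set(all_tissues)
        if extra:
            raise ValueError(f"TE {acc.id} accessible in unknown tissues {sorted(extra)}")
    counts: dict[str, int] = {}
    for acc in accessible:
        counts[acc.sharing(n_total)] = counts.get(acc.sharing(n_total), 0) + 1
    return counts


def te_class_composition(
    accessible: Sequence[AccessibleTE], by_tissue: bool = False
) -> dict:
    """Fractions of accessible TEs per class, overall or per tissue."""

    def fractions(tes: Sequence[AccessibleTE]) -> dict[str, float]:
        n = len(tes)
        if n == 0:
            return {}
        return {
            cls: sum(1 for t in tes if t.te.te_class == cls) / n for cls in TE_CLASSES
        }

    if not by_tissue:
        return fractions(accessible)
    tissues = sorted({t for acc in accessible for t in acc.tissues})
    return {
        tissue: fractions([acc for acc in accessible if tissue in acc.tissues])
        for tissue in tissues
    }


# ---------------------------------------------------------------------------
# permutation test


def _merged_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals)
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for iv in merged:
        starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
    return {c: (np.array(s), np.array(e)) for c, (s, e) in by_chrom.items()}


def _count_overlapping(
    starts: np.ndarray,
    ends: np.ndarray,
    ref: dict[str, tuple[np.ndarray, np.ndarray]],
    chroms: Sequence[str],
) -> int:
    """Number of query intervals overlapping >=1 merged reference interval."""
    n = 0
    for chrom in set(chroms):
        entry = ref.get(chrom)
        if entry is None:
            continue
        mask = np.array([c == chrom for c in chroms])
        qs, qe = starts[mask], ends[mask]
        rs, re = entry
        # first reference segment ending after the query start
        idx = np.searchsorted(re, qs, side="right")
        hit = (idx < rs.size) & (rs[np.minimum(idx, rs.size - 1)] < qe)
        n += int(hit.sum())
    return n


def _intersection_bp(
    starts: np.ndarray,
    ends: np.ndarray,
    ref: dict[str, tuple[np.ndarray, np.ndarray]],
    chroms: Sequence[str],
) -> int:
    """Shared bases between the union of the queries and the merged reference."""
    total = 0
    for chrom in set(chroms):
        entry = ref.get(chrom)
        if entry is None:
            continue
        mask = np.array([c == chrom for c in chroms])
        qiv = merge_intervals(
            [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts[mask], ends[mask])]
        )
        rs, re = entry
        for iv in qiv:
            lo = np.searchsorted(re, iv.start, side="right")
            hi = np.searchsorted(rs, iv.end, side="left")
            if hi > lo:
                total += int(
                    np.sum(
                        np.minimum(re[lo:hi], iv.end) - np.maximum(rs[lo:hi], iv.start)
                    )
                )
    return total


def permutation_enrichment(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    statistic: str = "n_overlapping_reference",
) -> PermutationResult:
    """Length-preserving uniform-shuffle permutation test.

    The null re-places every query interval uniformly at random on its own
    chromosome (overlaps among placed intervals permitted) and recomputes
    the statistic. ``n_overlapping_reference`` counts query intervals
    overlapping the reference; ``jaccard`` is intersection/union of covered
    bases. Fully reproducible given a seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("n_overlapping_reference", "jaccard"):
        raise ValueError(f"unknown statistic {statistic!r}")
    for iv in query:
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {iv.chrom}")
        if iv.length > chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} longer than its chromosome"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = _merged_arrays(reference)
    ref_total = sum(int((e - s).sum()) for s, e in ref.values())
    chroms = [iv.chrom for iv in query]
    lengths = np.array([iv.length for iv in query], dtype=np.int64)
    max_start = np.array(
        [chrom_lengths[c] for c in chroms], dtype=np.int64
    ) - lengths

    def stat(starts: np.ndarray, ends: np.ndarray) -> float:
        if statistic == "n_overlapping_reference":
            return float(_count_overlapping(starts, ends, ref, chroms))
        inter = _intersection_bp(starts, ends, ref, chroms)
        q_merged = merge_intervals(
            [
                GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(chroms, starts, ends)
            ]
        )
        q_total = sum(iv.length for iv in q_merged)
        union = q_total + ref_total - inter
        return inter / union if union > 0 else 0.0

    obs_starts = np.array([iv.start for iv in query], dtype=np.int64)
    observed = stat(obs_starts, obs_starts + lengths)
    null_values = []
    for _ in range(n_perm):
        starts = rng.integers(0, max_start + 1)
        null_values.append(stat(starts, starts + lengths))
    null_arr = np.array(null_values)
    p_enrich = (1 + int((null_arr >= observed).sum())) / (1 + n_perm)
    p_deplete = (1 + int((null_arr <= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        observed=float(observed),
        null_values=tuple(float(v) for v in null_values),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
    )
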