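"""Regulatory annotation of trait-associated variants.

Variants (reported 1-based, converted internally) are tested for
containment in atlas peaks; because atlas peaks are merged they are
disjoint, so each variant hits at most one peak. Candidate effector genes
for an in-peak variant are the significant peak-gene links of its peak,
ordered by ascending q, then descending |rho|, then gene id — a total
order, so prioritization is stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak
from .io import Variant
from .links import PeakGeneLink
from .te import PermutationResult, permutation_enrichment


@dataclass
class VariantAnnotation:
    variant: Variant
    peak_id: str | None
    linked_genes: list[tuple[str, float, float]] = field(default_factory=list)  # (gene, rho, q)

    @property
    def in_peak(self) -> bool:
        return self.peak_id is not None


def annotate_variants(
    variants: Sequence[Variant], atlas_peaks: Sequence[Peak]
) -> list[VariantAnnotation]:
    """Containment of each variant position in the merged peak atlas."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in atlas_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    arrays = {}
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        arrays[chrom] = (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            ps,
        )
    out = []
    for v in variants:
        peak_id = None
        entry = arrays.get(v.chrom)
        if entry is not None:
            starts, ends, ps = entry
            i = int(np.searchsorted(starts, v.pos0, side="right")) - 1
            if i >= 0 and v.pos0 < ends[i]:
                peak_id = ps[i].id
        out.append(VariantAnnotation(variant=v, peak_id=peak_id))
    return out


def prioritize_genes(
    annotations: Sequence[VariantAnnotation],
    links: Sequence[PeakGeneLink],
) -> list[VariantAnnotation]:
    """Fill candidate effector genes from the significant link map."""
    sig_by_peak: dict[str, list[PeakGeneLink]] = {}
    for l in links:
        if l.significant:
            sig_by_peak.setdefault(l.peak_id, []).append(l)
    for ann in annotations:
        if ann.peak_id is None:
            ann.linked_genes = []
            continue
        ranked = sorted(
            sig_by_peak.get(ann.peak_id, []),
            key=lambda l: (l.q, -abs(l.rho), l.gene_id),
        )
        ann.linked_genes = [(l.gene_id, l.rho, l.q) for l in ranked]
    return list(annotations)


def variant_peak_enrichment(
    variants: Sequence[Variant],
    atlas_peaks: Sequence[Peak],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test for variants falling inside peaks more often than a
    uniform per-chromosome re-draw of their positions.

    The observed statistic equals the in-peak count from
    :func:`annotate_variants` on the same input.
    """
    points = [GenomicInterval(v.chrom, v.pos0, v.pos0 + 1) for v in variants]
    reference = [p.interval for p in atlas_peaks]
    return permutation_enrichment(
        points,
        reference,
        chrom_lengths,
        n_perm=n_perm,
        seed=seed,
        statistic="n_overlapping_reference",
    )
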