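"""Genomic interval arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)`` —
the BED convention. Inputs that are natively 1-based inclusive (GTF-like
gene models, RepeatMasker ``.out``) are converted on read by
:mod:`pigatlas.io` so that every downstream computation uses a single
arithmetic convention.

Chromosome names are opaque strings: no ``chr`` prefix normalisation is
attempted, and a name mismatch between two inputs simply surfaces as zero
overlap (plus a warning from :func:`find_overlaps`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

TE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0


@dataclass(frozen=True)
class Peak:
    """A called or merged accessibility peak.

    ``center`` anchors every distance computation in the pipeline (distance
    to TSS, the 500 kb candidate window for peak-gene links).
    """

    interval: GenomicInterval
    id: str

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    @staticmethod
    def auto_id(chrom: str, start: int, end: int) -> str:
        return f"{chrom}:{start}-{end}"

    @classmethod
    def from_coords(cls, chrom: str, start: int, end: int, id: str | None = None) -> "Peak":
        iv = GenomicInterval(chrom, start, end)
        return cls(iv, id if id is not None else cls.auto_id(chrom, start, end))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-aware TSS and exonic feature annotation.

    ``features`` holds ``(category, interval)`` pairs with category in
    {CDS, UTR5, UTR3, exon}. The TSS is the 5' end of the gene span given
    the strand: ``start`` for ``+`` genes, ``end - 1`` for ``-`` genes
    (0-based position of the first transcribed base).
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    features: tuple[tuple[str, GenomicInterval], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"gene {self.id}: bad span {self.start}-{self.end}")
        for cat, iv in self.features:
            if iv.chrom != self.chrom:
                raise ValueError(f"gene {self.id}: feature {cat} on {iv.chrom} != {self.chrom}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def parse_te_class(class_family: str) -> str:
    """Map a RepeatMasker class/family string to a coarse TE class.

    The text before the first ``/`` (e.g. ``SINE/tRNA`` -> ``SINE``) is
    matched against SINE/LINE/LTR/DNA; anything else becomes ``Other``.
    """
    head = class_family.split("/", 1)[0].strip()
    return head if head in ("SINE", "LINE", "LTR", "DNA") else "Other"


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker repeat record (a transposable-element copy)."""

    interval: GenomicInterval
    te_class: str
    family: str
    name: str

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}|{self.name}"

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose spans touch or come within ``gap`` bp.

    With the default ``gap=0`` book-ended intervals (``a.end == b.start``)
    are merged, matching the ``bedtools merge`` default used to build the
    peak atlas. The result is sorted by (chrom, start) and covers exactly
    the same set of bases as the input (plus bridged gaps when gap > 0).
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and out[-1].end + gap >= iv.start:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two half-open intervals (0 across chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals per chromosome; tree payloads are input indices."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All (query index, subject index, overlap bp) pairs with overlap > 0.

    Output is sorted by query index then subject index. If the two inputs
    share no chromosome names at all (and both are non-empty) a warning is
    emitted listing the names private to each side, since that usually
    means inconsistent naming rather than true disjointness.
    """
    q_chroms = {iv.chrom for iv in query}
    s_chroms = {iv.chrom for iv in subject}
    if query and subject and not (q_chroms & s_chroms):
        warnings.warn(
            "no shared chromosome names between query and subject: "
            f"query-only={sorted(q_chroms)}, subject-only={sorted(s_chroms)}",
            stacklevel=2,
        )
    trees = build_trees(subject)
    hits: list[tuple[int, int, int]] = []
    for qi, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for node in tree.overlap(q.start, q.end):
            si = node.data
            hits.append((qi, si, min(q.end, node.end) - max(q.start, node.begin)))
    hits.sort(key=lambda t: (t[0], t[1]))
    return hits
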