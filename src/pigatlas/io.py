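"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* BED3/BED4, tab-separated, 0-based half-open (native convention).
* RepeatMasker ``.out``: 3 header lines, whitespace-delimited records,
  1-based inclusive coordinates (converted on read).
* GTF-like gene models: 9 tab-separated columns, 1-based inclusive
  coordinates, ``gene_id "..."`` attribute (converted on read).
* TSV matrices (feature id in the first column, sample ids as header).
* Sample sheet, chromosome-length and variant TSVs.

All readers accept plain or gzip-compressed files (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, TEAnnotation, parse_te_class


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED4 peaks; ids default to ``chrom:start-end``."""
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            pid = fields[3] if len(fields) >= 4 and fields[3] != "" else None
            peaks.append(Peak.from_coords(chrom, start, end, pid))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "    repeat          position in repeat\n"
    "score   div. del. ins.  sequence  begin  end   (left)  repeat"
    "          class/family  begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[TEAnnotation]:
    """Parse RepeatMasker ``.out``: skip 3 header lines, convert 1-based
    inclusive begin/end to 0-based half-open ``(begin-1, end)``."""
    tes: list[TEAnnotation] = []
    with _open_text(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: expected 3 header lines, file has {len(lines)}")
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ParseError(f"{path}: line {lineno}: expected >=11 fields")
        chrom = fields[4]
        try:
            begin, end = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric coordinates") from exc
        if begin < 1 or end < begin:
            raise ParseError(f"{path}: line {lineno}: invalid 1-based span {begin}-{end}")
        name, class_family = fields[9], fields[10]
        tes.append(
            TEAnnotation(
                interval=GenomicInterval(chrom, begin - 1, end),
                te_class=parse_te_class(class_family),
                family=class_family,
                name=name,
            )
        )
    return tes


def write_repeatmasker_out(tes: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write a RepeatMasker-style table (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as fh:
        fh.write(RM_HEADER)
        for i, te in enumerate(tes, start=1):
            iv = te.interval
            fh.write(
                f"  239   11.4  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}  "
                f"(0)  +  {te.name}  {te.family}  1  {iv.length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# GTF-like gene models

_FEATURE_ALIASES = {
    "cds": "CDS",
    "five_prime_utr": "UTR5",
    "5utr": "UTR5",
    "utr5": "UTR5",
    "three_prime_utr": "UTR3",
    "3utr": "UTR3",
    "utr3": "UTR3",
    "exon": "exon",
}


def _gene_id_from_attributes(attrs: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read GTF-like gene models (1-based inclusive on disk).

    ``gene`` records define the span and strand; CDS/UTR/exon records
    become features. A gene without an explicit ``gene`` record takes the
    envelope of its features.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}  # id -> chrom, strand, start, end
    feats: dict[str, list[tuple[str, GenomicInterval]]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: missing or bad strand {strand!r}")
            gid = _gene_id_from_attributes(attrs)
            if gid is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id")
            start0, end0 = start1 - 1, end1
            if gid not in spans and gid not in feats:
                order.append(gid)
            if ftype.lower() == "gene":
                spans[gid] = (chrom, strand, start0, end0)
            else:
                cat = _FEATURE_ALIASES.get(ftype.lower())
                if cat is None:
                    continue
                feats.setdefault(gid, []).append(
                    (cat, GenomicInterval(chrom, start0, end0))
                )
                if gid not in spans:
                    spans[gid] = (chrom, strand, start0, end0)
                else:
                    c, s, a, b = spans[gid]
                    spans[gid] = (c, s, min(a, start0), max(b, end0))
    genes = []
    for gid in order:
        chrom, strand, start, end = spans[gid]
        genes.append(
            GeneModel(
                id=gid,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                features=tuple(feats.get(gid, [])),
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        feature_types = {"CDS": "CDS", "UTR5": "five_prime_utr", "UTR3": "three_prime_utr", "exon": "exon"}
        for g in genes:
            attrs = f'gene_id "{g.id}";'
            fh.write(
                f"{g.chrom}\tpigatlas\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for cat, iv in g.features:
                fh.write(
                    f"{g.chrom}\tpigatlas\t{feature_types[cat]}\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# tabular files


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample matrix: first column feature id, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            lengths[fields[0]] = int(fields[1])
    return lengths


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class Variant:
    """A trait-associated variant at a conventionally 1-based position."""

    id: str
    chrom: str
    pos: int  # 1-based, as reported in GWAS tables
    trait: str = ""
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: 1-based pos must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position used for peak containment tests."""
        return self.pos - 1


def read_variants(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    required = {"id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: variant table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Variant(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                trait=str(getattr(row, "trait", "")),
                p_value=float(getattr(row, "p_value", float("nan"))),
            )
        )
    return out


def write_variants(variants: Iterable[Variant], path: str | Path) -> None:
    rows = [
        {"id": v.id, "chrom": v.chrom, "pos": v.pos, "trait": v.trait, "p_value": v.p_value}
        for v in variants
    ]
    pd.DataFrame(rows, columns=["id", "chrom", "pos", "trait", "p_value"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
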