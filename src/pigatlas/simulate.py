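"""Synthetic multi-tissue ATAC/RNA study with planted truth.

The generator emulates, at desk scale, the structure of a multi-tissue
chromatin-accessibility atlas with paired expression data: several
tissues with two biological replicates each; a merged set of peaks whose
accessibility is tissue-specific, broadly shared, or ubiquitous;
negative-binomial in-peak read counts; gene expression coupled to the
realized intensity of a nearby peak with positive or negative sign; TEs
placed to just-pass or just-fail the 50%/20% accessibility criterion; and
trait variants planted inside and outside peaks.

Planted structure:

* ``frac_specific`` of peaks are open only in one target tissue (baseline
  intensity times ``specific_fold`` there, ``background_rel`` of baseline
  elsewhere) — a tissue-specific peak is closed, not merely weaker, in
  the other tissues.
* ``frac_conserved`` of peaks are open everywhere at baseline.
* The remaining peaks are broadly shared: each tissue is included with
  probability ``presence_prob`` (resampled until at least two tissues are
  present). Broad sharing dominates real atlases, and it is what keeps the
  two-fold specificity rule precise: a flat peak seen in only two tissues
  crosses an inclusive two-fold ratio far too easily by replicate noise
  alone.

All randomness flows from numpy's PCG64 generator seeded from
``(stage tag, config.seed)``, so each stage is independently reproducible
and byte-identical across runs and platforms.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, TEAnnotation
from . import io as pio
from .links import candidate_pairs
from .quantify import IntensityMatrix, SampleSheet, ppkm_normalize, tpm_normalize

# stage tags for per-stage generator streams
_STAGE_GENOME, _STAGE_ATLAS, _STAGE_EXPR, _STAGE_TES, _STAGE_VARIANTS = range(5)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study design at
    desk scale (tissues x replicates layout, tissue-specific and ubiquitous
    peaks, cis-linked expression, boundary-placed TEs, in/out variants)."""

    seed: int = 1
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 500
    n_tissues: int = 4
    n_replicates: int = 2
    n_peaks: int = 2000
    frac_specific: float = 0.2
    frac_conserved: float = 0.05
    specific_fold: float = 4.0
    nb_dispersion: float = 0.2
    mean_depth: float = 2_000_000.0
    n_true_links: int = 100
    link_effect: float = 3.0
    frac_negative_links: float = 0.3
    noise_sd: float = 0.5
    n_tes: int = 1000
    te_accessible_frac: float = 0.2
    n_variants_in_peaks: int = 20
    n_variants_outside: int = 80
    # secondary shape parameters
    presence_prob: float = 0.97
    background_rel: float = 0.02
    detection_floor: int = 100
    peak_width_min: int = 300
    peak_width_max: int = 700
    gene_length_min: int = 2000
    gene_length_max: int = 5000
    library_sigma: float = 0.1
    baseline_sigma: float = 1.0
    expression_baseline_low: float = 50.0
    expression_baseline_high: float = 150.0
    link_window: int = 500_000

    def __post_init__(self) -> None:
        for name in ("frac_specific", "frac_conserved", "frac_negative_links",
                     "te_accessible_frac", "presence_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.specific_fold <= 1:
            raise ValueError("specific_fold must exceed 1")
        if min(self.n_chrom, self.n_tissues, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass
class SyntheticTruth:
    """Planted labels for recovery tests."""

    specific_peaks: dict[str, str] = field(default_factory=dict)  # peak id -> tissue
    conserved_peaks: set[str] = field(default_factory=set)
    true_links: list[tuple[str, str, str, float]] = field(default_factory=list)
    accessible_tes: dict[str, list[str]] = field(default_factory=dict)  # te id -> tissues
    failing_tes: set[str] = field(default_factory=set)
    in_peak_variants: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "specific_peaks": self.specific_peaks,
            "conserved_peaks": sorted(self.conserved_peaks),
            "true_links": [list(t) for t in self.true_links],
            "accessible_tes": {k: sorted(v) for k, v in sorted(self.accessible_tes.items())},
            "failing_tes": sorted(self.failing_tes),
            "in_peak_variants": sorted(self.in_peak_variants),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# genome


def _pack_intervals(
    rng: np.random.Generator,
    chrom: str,
    chrom_length: int,
    lengths: Sequence[int],
    min_gap: int = 1,
) -> list[GenomicInterval]:
    """Place non-overlapping intervals of the given lengths uniformly.

    A minimum gap of 1 bp keeps independently placed intervals from being
    book-ended, so merging never fuses two planted intervals.
    """
    n = len(lengths)
    total = int(sum(lengths)) + min_gap * max(0, n - 1)
    slack = chrom_length - total
    if slack < 0:
        raise ValueError(
            f"cannot pack {n} intervals of {total} bp into {chrom_length} bp"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    out = []
    cum = 0
    for i, (off, ln) in enumerate(zip(offsets, lengths)):
        start = int(off) + cum + i * min_gap
        out.append(GenomicInterval(chrom, start, start + int(ln)))
        cum += int(ln)
    return out


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping single-exon genes (UTR5-CDS-UTR3) on random strands."""
    rng = config._rng(_STAGE_GENOME)
    chroms = list(config.chrom_lengths)
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, size=n)
        spans = _pack_intervals(rng, chrom, config.chrom_length, lengths)
        strands = rng.choice(["+", "-"], size=n)
        for span, strand in zip(spans, strands):
            gi += 1
            u5 = int(rng.integers(100, 301))
            u3 = int(rng.integers(100, 301))
            s, e = span.start, span.end
            if strand == "+":
                features = (
                    ("UTR5", GenomicInterval(chrom, s, s + u5)),
                    ("CDS", GenomicInterval(chrom, s + u5, e - u3)),
                    ("UTR3", GenomicInterval(chrom, e - u3, e)),
                    ("exon", GenomicInterval(chrom, s, e)),
                )
            else:
                features = (
                    ("UTR3", GenomicInterval(chrom, s, s + u3)),
                    ("CDS", GenomicInterval(chrom, s + u3, e - u5)),
                    ("UTR5", GenomicInterval(chrom, e - u5, e)),
                    ("exon", GenomicInterval(chrom, s, e)),
                )
            genes.append(
                GeneModel(
                    id=f"gene{gi:04d}",
                    chrom=chrom,
                    strand=str(strand),
                    start=s,
                    end=e,
                    features=features,
                )
            )
    return genes, config.chrom_lengths


# ---------------------------------------------------------------------------
# atlas (peaks, per-sample calls, counts)


@dataclass
class SimulatedAtlas:
    sheet: SampleSheet
    peaks: list[Peak]
    per_sample_peaks: dict[str, list[Peak]]
    counts: IntensityMatrix
    tissue_of_sample: dict[str, str]


def simulate_atlas(
    config: SimulationConfig, genome: tuple[list[GeneModel], dict[str, int]]
) -> tuple[SimulatedAtlas, SyntheticTruth]:
    rng = config._rng(_STAGE_ATLAS)
    _, chrom_lengths = genome
    chroms = list(chrom_lengths)

    per_chrom = [config.n_peaks // config.n_chrom] * config.n_chrom
    for i in range(config.n_peaks % config.n_chrom):
        per_chrom[i] += 1
    peaks: list[Peak] = []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        widths = rng.integers(config.peak_width_min, config.peak_width_max + 1, size=n)
        for iv in _pack_intervals(rng, chrom, chrom_lengths[chrom], widths):
            peaks.append(Peak.from_coords(iv.chrom, iv.start, iv.end))
    n_peaks = len(peaks)

    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]
    records = [
        (f"{t}_rep{r + 1}", t, r + 1) for t in tissues for r in range(config.n_replicates)
    ]
    sheet = SampleSheet.from_records(records)
    tissue_of_sample = {sid: t for sid, t, _ in records}

    # planted class assignment
    truth = SyntheticTruth()
    order = rng.permutation(n_peaks)
    n_spec = round(config.frac_specific * n_peaks)
    n_cons = round(config.frac_conserved * n_peaks)
    spec_idx = order[:n_spec]
    cons_idx = order[n_spec : n_spec + n_cons]
    other_idx = order[n_spec + n_cons :]

    # relative intensity of each peak in each tissue
    rel = np.full((n_peaks, config.n_tissues), config.background_rel)
    spec_tissue = rng.integers(0, config.n_tissues, size=n_spec)
    for i, t in zip(spec_idx, spec_tissue):
        rel[i, t] = config.specific_fold
        truth.specific_peaks[peaks[i].id] = tissues[t]
    rel[cons_idx, :] = 1.0
    truth.conserved_peaks = {peaks[i].id for i in cons_idx}
    if config.n_tissues >= 2:
        for i in other_idx:
            while True:
                present = rng.random(config.n_tissues) < config.presence_prob
                if present.sum() >= 2:
                    break
            rel[i, present] = 1.0
    else:
        rel[other_idx, :] = 1.0

    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_peaks)
    lengths_kb = np.array([p.length for p in peaks]) / 1e3

    sample_ids = [sid for sid, _, _ in records]
    lib = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=len(sample_ids))
    counts = np.zeros((n_peaks, len(sample_ids)), dtype=np.int64)
    for j, (sid, tissue, _) in enumerate(records):
        t = tissues.index(tissue)
        weight = base * rel[:, t] * lengths_kb
        mu = config.mean_depth * lib[j] * weight / weight.sum()
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    counts_df = pd.DataFrame(
        counts, index=[p.id for p in peaks], columns=sample_ids
    )
    per_sample_peaks = {
        sid: [p for i, p in enumerate(peaks) if counts[i, j] >= config.detection_floor]
        for j, sid in enumerate(sample_ids)
    }
    atlas = SimulatedAtlas(
        sheet=sheet,
        peaks=peaks,
        per_sample_peaks=per_sample_peaks,
        counts=IntensityMatrix(counts_df, "counts"),
        tissue_of_sample=tissue_of_sample,
    )
    return atlas, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    genome: tuple[list[GeneModel], dict[str, int]],
    atlas: SimulatedAtlas,
    truth: SyntheticTruth,
) -> IntensityMatrix:
    """TPM matrix with ``n_true_links`` genes coupled to the realized
    intensity of one nearby peak (positive or negative sign); all other
    genes are independent noise around a flat baseline. True links are
    appended to ``truth.true_links``."""
    rng = config._rng(_STAGE_EXPR)
    genes, _ = genome
    ppkm = ppkm_normalize(atlas.counts, {p.id: p.length for p in atlas.peaks})
    pairs = candidate_pairs(atlas.peaks, genes, window=config.link_window)
    if config.n_true_links > 0 and not pairs:
        raise ValueError("no candidate peak-gene pairs within the link window")

    perm = rng.permutation(len(pairs))
    chosen: list[tuple[str, str, int]] = []
    used_genes: set[str] = set()
    used_peaks: set[str] = set()
    for k in perm:
        peak_id, gene_id, _ = pairs[k]
        if gene_id in used_genes or peak_id in used_peaks:
            continue
        chosen.append(pairs[k])
        used_genes.add(gene_id)
        used_peaks.add(peak_id)
        if len(chosen) == config.n_true_links:
            break
    if len(chosen) < config.n_true_links:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_true_links} true links"
        )

    n_neg = round(config.frac_negative_links * len(chosen))
    signs = [-1.0] * n_neg + [1.0] * (len(chosen) - n_neg)

    gene_ids = [g.id for g in genes]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_samples = len(ppkm.col_ids)
    baseline = rng.uniform(
        config.expression_baseline_low, config.expression_baseline_high, size=len(genes)
    )
    expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))
    ppkm_values = ppkm.df.to_numpy()
    peak_row = {pid: i for i, pid in enumerate(ppkm.row_ids)}
    for (peak_id, gene_id, _), s in zip(chosen, signs):
        x = np.log1p(ppkm_values[peak_row[peak_id]])
        gi = gene_index[gene_id]
        expr[gi] = (
            baseline[gi]
            + s * config.link_effect * x
            + rng.normal(0.0, config.noise_sd, size=n_samples)
        )
        truth.true_links.append(
            (peak_id, gene_id, "negative" if s < 0 else "positive", config.link_effect)
        )
    expr = np.clip(expr, 0.0, None)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=ppkm.col_ids)
    gene_lengths = {g.id: g.end - g.start for g in genes}
    return tpm_normalize(IntensityMatrix(expr_df, "counts"), gene_lengths)


# ---------------------------------------------------------------------------
# transposable elements


def _called_tissues_by_peak(atlas: SimulatedAtlas) -> dict[str, list[str]]:
    """Tissues whose call set (any replicate) contains each planted peak."""
    sample_sets = {sid: {p.id for p in ps} for sid, ps in atlas.per_sample_peaks.items()}
    out: dict[str, list[str]] = {p.id: [] for p in atlas.peaks}
    for tissue in atlas.sheet.tissues:
        called: set[str] = set()
        for sid in atlas.sheet.samples_of(tissue):
            called |= sample_sets[sid]
        for pid in called:
            out[pid].append(tissue)
    return out


_TE_CLASS_WEIGHTS = {"SINE": 0.40, "LINE": 0.30, "LTR": 0.23, "DNA": 0.07}


def simulate_tes(
    config: SimulationConfig, atlas: SimulatedAtlas
) -> tuple[list[TEAnnotation], SyntheticTruth]:
    """RepeatMasker-style TE set exercising the 50%/20% criterion boundary.

    A ``te_accessible_frac`` subset is placed to overlap a called peak by
    exactly the binding arm of the criterion (just-passing); an equally
    sized subset overlaps one base less (just-failing, guaranteed not
    accessible); the remainder is placed uniformly. Returns the TEs and a
    truth object whose ``accessible_tes`` maps just-passing TEs to the
    tissues whose call sets contain the host peak.
    """
    rng = config._rng(_STAGE_TES)
    truth = SyntheticTruth()
    chrom_lengths = config.chrom_lengths

    peaks_sorted = sorted(atlas.peaks, key=lambda p: (p.chrom, p.start))
    next_start: dict[str, dict[str, int]] = {}
    for a, b in zip(peaks_sorted, peaks_sorted[1:]):
        if a.chrom == b.chrom:
            next_start.setdefault(a.chrom, {})[a.id] = b.start
    called_tissues = _called_tissues_by_peak(atlas)

    def right_gap(p: Peak) -> int:
        nxt = next_start.get(p.chrom, {}).get(p.id)
        end_of_chrom = chrom_lengths[p.chrom]
        return (nxt if nxt is not None else end_of_chrom) - p.end

    candidates = [
        p
        for p in atlas.peaks
        if called_tissues[p.id] and right_gap(p) > p.length + 1
    ]
    n_boundary = round(config.te_accessible_frac * config.n_tes)
    if 2 * n_boundary > len(candidates):
        raise ValueError("not enough isolated called peaks to host boundary TEs")
    host_idx = rng.choice(len(candidates), size=2 * n_boundary, replace=False)
    hosts = [candidates[i] for i in host_idx]

    classes = list(_TE_CLASS_WEIGHTS)
    weights = np.array(list(_TE_CLASS_WEIGHTS.values()))

    tes: list[TEAnnotation] = []

    def make_te(chrom: str, start: int, length: int, k: int) -> TEAnnotation:
        cls = str(rng.choice(classes, p=weights / weights.sum()))
        return TEAnnotation(
            interval=GenomicInterval(chrom, start, start + length),
            te_class=cls,
            family=f"{cls}/fam{int(rng.integers(1, 10))}",
            name=f"te{k:05d}",
        )

    k = 0
    for mode, host in zip(["pass"] * n_boundary + ["fail"] * n_boundary, hosts):
        lp = host.length
        lt = int(rng.integers(max(1, int(0.4 * lp)), lp + 1))
        o = max(math.ceil(0.5 * lt), math.ceil(0.2 * lp))
        if mode == "fail":
            o -= 1
        start = host.end - o
        k += 1
        te = make_te(host.chrom, start, lt, k)
        tes.append(te)
        if mode == "pass":
            truth.accessible_tes[te.id] = sorted(called_tissues[host.id])
        else:
            truth.failing_tes.add(te.id)

    n_rest = config.n_tes - 2 * n_boundary
    for _ in range(max(0, n_rest)):
        chrom = str(rng.choice(list(chrom_lengths)))
        lt = int(rng.integers(150, 2001))
        start = int(rng.integers(0, chrom_lengths[chrom] - lt + 1))
        k += 1
        tes.append(make_te(chrom, start, lt, k))
    return tes, truth


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    config: SimulationConfig, atlas: SimulatedAtlas
) -> tuple[list[pio.Variant], SyntheticTruth]:
    """Exactly ``n_variants_in_peaks`` positions inside peak spans and
    ``n_variants_outside`` in the complement."""
    rng = config._rng(_STAGE_VARIANTS)
    truth = SyntheticTruth()
    chrom_lengths = config.chrom_lengths
    if config.n_variants_in_peaks > 0 and not atlas.peaks:
        raise ValueError("cannot plant in-peak variants without peaks")
    peak_cover = {
        chrom: sorted(
            (p.start, p.end) for p in atlas.peaks if p.chrom == chrom
        )
        for chrom in chrom_lengths
    }

    def in_any_peak(chrom: str, pos0: int) -> bool:
        spans = peak_cover[chrom]
        i = bisect.bisect_right(spans, (pos0, math.inf)) - 1
        return i >= 0 and spans[i][0] <= pos0 < spans[i][1]

    total_cover = sum(e - s for spans in peak_cover.values() for s, e in spans)
    total_genome = sum(chrom_lengths.values())
    if config.n_variants_outside > 0 and total_cover >= total_genome:
        raise ValueError("no bases outside peaks to place variants")

    variants: list[pio.Variant] = []
    vi = 0
    for _ in range(config.n_variants_in_peaks):
        p = atlas.peaks[int(rng.integers(0, len(atlas.peaks)))]
        pos0 = int(rng.integers(p.start, p.end))
        vi += 1
        v = pio.Variant(
            id=f"var{vi:04d}",
            chrom=p.chrom,
            pos=pos0 + 1,
            trait="trait1",
            p_value=float(10 ** -rng.uniform(6, 12)),
        )
        variants.append(v)
        truth.in_peak_variants.add(v.id)
    for _ in range(config.n_variants_outside):
        while True:
            chrom = str(rng.choice(list(chrom_lengths)))
            pos0 = int(rng.integers(0, chrom_lengths[chrom]))
            if not in_any_peak(chrom, pos0):
                break
        vi += 1
        variants.append(
            pio.Variant(
                id=f"var{vi:04d}",
                chrom=chrom,
                pos=pos0 + 1,
                trait="trait1",
                p_value=float(10 ** -rng.uniform(6, 12)),
            )
        )
    return variants, truth


# ---------------------------------------------------------------------------
# whole study


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    atlas: SimulatedAtlas
    tpm: IntensityMatrix
    tes: list[TEAnnotation]
    variants: list[pio.Variant]
    truth: SyntheticTruth


def _merge_truth(*parts: SyntheticTruth) -> SyntheticTruth:
    out = SyntheticTruth()
    for t in parts:
        out.specific_peaks.update(t.specific_peaks)
        out.conserved_peaks |= t.conserved_peaks
        out.true_links.extend(t.true_links)
        out.accessible_tes.update(t.accessible_tes)
        out.failing_tes |= t.failing_tes
        out.in_peak_variants |= t.in_peak_variants
    return out


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage and bundle the result."""
    genome = simulate_genome(config)
    atlas, truth_atlas = simulate_atlas(config, genome)
    tpm = simulate_expression(config, genome, atlas, truth_atlas)
    tes, truth_tes = simulate_tes(config, atlas)
    variants, truth_var = simulate_variants(config, atlas)
    genes, chrom_lengths = genome
    return SimulatedStudy(
        config=config,
        genes=genes,
        chrom_lengths=chrom_lengths,
        atlas=atlas,
        tpm=tpm,
        tes=tes,
        variants=variants,
        truth=_merge_truth(truth_atlas, truth_tes, truth_var),
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the pipeline reads, plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    beds = outdir / "peaks"
    beds.mkdir(exist_ok=True)
    for sid, peaks in study.atlas.per_sample_peaks.items():
        p = beds / f"{sid}.bed"
        pio.write_bed(peaks, p)
        paths[f"bed:{sid}"] = p
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    study.atlas.sheet.write_tsv(paths["sample_sheet"])
    paths["counts"] = outdir / "peak_counts.tsv"
    pio.write_matrix_tsv(study.atlas.counts.df, paths["counts"], index_label="peak_id")
    paths["tpm"] = outdir / "gene_tpm.tsv"
    pio.write_matrix_tsv(study.tpm.df, paths["tpm"], index_label="gene_id")
    paths["genes"] = outdir / "genes.gtf"
    pio.write_gene_models(study.genes, paths["genes"])
    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    pio.write_chrom_lengths(study.chrom_lengths, paths["chrom_lengths"])
    paths["tes"] = outdir / "repeats.out"
    pio.write_repeatmasker_out(study.tes, paths["tes"])
    paths["variants"] = outdir / "variants.tsv"
    pio.write_variants(study.variants, paths["variants"])
    paths["truth"] = outdir / "truth.json"
    study.truth.to_json(paths["truth"])
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(asdict(study.config), indent=1, sort_keys=True))
    paths["config"] = config_path
    return paths
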