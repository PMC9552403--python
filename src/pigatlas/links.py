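"""The peak-gene correlation map.

Candidate pairs are peaks and genes on the same chromosome whose TSS lies
within a cis window (default 500 kb, inclusive) of the peak center. Each
pair is scored by Spearman correlation between peak intensity (PPKM) and
gene expression (TPM) across the shared samples; two-sided p-values come
from the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
freedom. Benjamini-Hochberg adjustment is applied once, jointly across
all tested pairs, and a link is significant when q < alpha (strict).

Signed distance is TSS - peak center, negated for minus-strand genes, so
a positive distance always means the peak lies 5' (upstream) of the gene.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, Peak
from .quantify import IntensityMatrix


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int  # signed, strand-adjusted bp
    rho: float
    p: float
    q: float
    significant: bool
    sign: str  # "positive" or "negative"


@dataclass(frozen=True)
class SignProfile:
    peak_id: str
    n_pos: int
    n_neg: int

    @property
    def label(self) -> str:
        if self.n_pos and self.n_neg:
            return "mixed"
        return "positive_only" if self.n_pos else "negative_only"


def candidate_pairs(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], window: int = 500_000
) -> list[tuple[str, str, int]]:
    """(peak_id, gene_id, signed distance) for same-chromosome pairs with
    |TSS - center| <= window (inclusive)."""
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.id))
        arrays[chrom] = (np.array([g.tss for g in gs]), gs)
    pairs: list[tuple[str, str, int]] = []
    for p in peaks:
        entry = arrays.get(p.chrom)
        if entry is None:
            continue
        tss_arr, gs = entry
        lo = int(np.searchsorted(tss_arr, p.center - window, side="left"))
        hi = int(np.searchsorted(tss_arr, p.center + window, side="right"))
        for g in gs[lo:hi]:
            raw = g.tss - p.center
            signed = raw if g.strand == "+" else -raw
            pairs.append((p.id, g.id, signed))
    return pairs


# ---------------------------------------------------------------------------
# correlation machinery


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    return float(xd @ yd) / denom


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman correlation with a two-sided p-value.

    ``method="t"`` uses the t approximation (standard at the sample sizes
    of a multi-tissue atlas); ``method="exact"`` enumerates all rank
    permutations and is only sensible for n < 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no defined rank correlation")
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    rho = max(-1.0, min(1.0, rho))
    if method == "t":
        return rho, _t_pvalue(rho, n)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.array(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    p-values, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def build_link_map(
    ppkm: IntensityMatrix,
    tpm: IntensityMatrix,
    pairs: Iterable[tuple[str, str, int]],
    alpha: float = 0.01,
    min_complete: int = 5,
) -> tuple[list[PeakGeneLink], int]:
    """Score every candidate pair and adjust jointly.

    Pairs with a constant intensity or expression vector (or fewer than
    ``min_complete`` complete observations after dropping missing values)
    are excluded from testing and from the BH denominator; their count is
    returned alongside the links.
    """
    if list(ppkm.col_ids) != list(tpm.col_ids):
        raise ValueError("ppkm and tpm must share identical sample columns in order")
    pairs = list(pairs)
    peak_index = {pid: i for i, pid in enumerate(ppkm.row_ids)}
    gene_index = {gid: i for i, gid in enumerate(tpm.row_ids)}
    pv = ppkm.df.to_numpy(dtype=float)
    gv = tpm.df.to_numpy(dtype=float)

    # rank-transform each row once; constant rows flagged as degenerate
    def rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ranks = np.apply_along_axis(_rank, 1, values) if values.size else values
        constant = np.all(values == values[:, :1], axis=1) if values.size else np.array([])
        if ranks.size:
            mu = ranks.mean(axis=1, keepdims=True)
            ranks = ranks - mu
            norm = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
            with np.errstate(invalid="ignore", divide="ignore"):
                ranks = np.where(norm > 0, ranks / norm, 0.0)
        return ranks, constant

    has_nan = np.isnan(pv).any() or np.isnan(gv).any()
    n_samples = pv.shape[1]
    degenerate = 0
    tested: list[tuple[str, str, int, float, float]] = []
    if not has_nan:
        pr, p_const = rank_rows(pv)
        gr, g_const = rank_rows(gv)
        for peak_id, gene_id, dist in pairs:
            pi, gi = peak_index.get(peak_id), gene_index.get(gene_id)
            if pi is None or gi is None:
                raise KeyError(f"pair ({peak_id}, {gene_id}) not present in matrices")
            if p_const[pi] or g_const[gi] or n_samples < min_complete:
                degenerate += 1
                continue
            rho = float(pr[pi] @ gr[gi])
            rho = max(-1.0, min(1.0, rho))
            tested.append((peak_id, gene_id, dist, rho, _t_pvalue(rho, n_samples)))
    else:
        for peak_id, gene_id, dist in pairs:
            pi, gi = peak_index.get(peak_id), gene_index.get(gene_id)
            if pi is None or gi is None:
                raise KeyError(f"pair ({peak_id}, {gene_id}) not present in matrices")
            x, y = pv[pi], gv[gi]
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < min_complete or np.all(x == x[0]) or np.all(y == y[0]):
                degenerate += 1
                continue
            rho = _pearson(_rank(x), _rank(y))
            rho = max(-1.0, min(1.0, rho))
            tested.append((peak_id, gene_id, dist, rho, _t_pvalue(rho, x.size)))

    qs = bh_adjust([t[4] for t in tested]) if tested else np.array([])
    links = [
        PeakGeneLink(
            peak_id=peak_id,
            gene_id=gene_id,
            distance=dist,
            rho=rho,
            p=p,
            q=float(q),
            significant=bool(q < alpha),
            sign="positive" if rho > 0 else "negative",
        )
        for (peak_id, gene_id, dist, rho, p), q in zip(tested, qs)
    ]
    return links, degenerate


# ---------------------------------------------------------------------------
# summaries of the significant map


def classify_sign_profiles(
    links: Sequence[PeakGeneLink],
) -> tuple[list[SignProfile], dict[str, float], dict[str, float]]:
    """Per-peak sign profiles of the significant links.

    Returns the profiles, association-level fractions (each significant
    association labelled with its peak's profile) and peak-level fractions.
    Both tallies are reported because "positive only / negative only /
    mixed" percentages can be counted over peaks or over associations.
    """
    sig = [l for l in links if l.significant]
    if not sig:
        raise ValueError("no significant links to classify")
    counts: dict[str, list[int]] = {}
    for l in sig:
        c = counts.setdefault(l.peak_id, [0, 0])
        c[0 if l.sign == "positive" else 1] += 1
    profiles = [
        SignProfile(peak_id=pid, n_pos=c[0], n_neg=c[1]) for pid, c in counts.items()
    ]
    label_of = {pr.peak_id: pr.label for pr in profiles}
    assoc_tally = {"positive_only": 0, "negative_only": 0, "mixed": 0}
    for l in sig:
        assoc_tally[label_of[l.peak_id]] += 1
    peak_tally = {"positive_only": 0, "negative_only": 0, "mixed": 0}
    for pr in profiles:
        peak_tally[pr.label] += 1
    assoc_frac = {k: v / len(sig) for k, v in assoc_tally.items()}
    peak_frac = {k: v / len(profiles) for k, v in peak_tally.items()}
    return profiles, assoc_frac, peak_frac


def link_summary(
    links: Sequence[PeakGeneLink], bin_width: int = 20_000
) -> dict:
    """Per-sign mean genes-per-peak / peaks-per-gene and a signed-distance
    histogram of the significant links."""
    out: dict = {"per_sign": {}, "histogram": {}}
    sig = [l for l in links if l.significant]
    for sign in ("positive", "negative"):
        subset = [l for l in sig if l.sign == sign]
        if not subset:
            out["per_sign"][sign] = {
                "n_links": 0,
                "genes_per_peak": None,
                "peaks_per_gene": None,
            }
            out["histogram"][sign] = {"bin_edges": [], "counts": []}
            continue
        genes_of_peak: dict[str, set[str]] = {}
        peaks_of_gene: dict[str, set[str]] = {}
        for l in subset:
            genes_of_peak.setdefault(l.peak_id, set()).add(l.gene_id)
            peaks_of_gene.setdefault(l.gene_id, set()).add(l.peak_id)
        distances = np.array([l.distance for l in subset])
        lo = math.floor(distances.min() / bin_width) * bin_width
        hi = math.ceil((distances.max() + 1) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        hist, _ = np.histogram(distances, bins=edges)
        out["per_sign"][sign] = {
            "n_links": len(subset),
            "genes_per_peak": float(np.mean([len(v) for v in genes_of_peak.values()])),
            "peaks_per_gene": float(np.mean([len(v) for v in peaks_of_gene.values()])),
        }
        out["histogram"][sign] = {
            "bin_edges": edges.tolist(),
            "counts": hist.tolist(),
        }
    return out
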