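"""Candidate windows, Spearman, BH adjustment and the link map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pigatlas.intervals import GeneModel, Peak
from pigatlas.links import (
    bh_adjust,
    build_link_map,
    candidate_pairs,
    classify_sign_profiles,
    link_summary,
    spearman,
    PeakGeneLink,
)
from pigatlas.quantify import IntensityMatrix, build_atlas


def gene(gid, chrom, strand, start, end):
    return GeneModel(id=gid, chrom=chrom, strand=strand, start=start, end=end)


class TestCandidatePairs:
    def test_window_boundary_inclusive(self):
        p = Peak.from_coords("chr1", 0, 1000, "p")  # center 500
        genes = [
            gene("at_edge", "chr1", "+", 500_500, 501_000),  # tss 500,500 -> distance 500,000
            gene("beyond", "chr1", "+", 500_501, 501_001),
        ]
        pairs = candidate_pairs([p], genes)
        assert [(g, d) for _, g, d in pairs] == [("at_edge", 500_000)]

    def test_other_chromosome_excluded(self):
        p = Peak.from_coords("chr1", 0, 1000, "p")
        assert candidate_pairs([p], [gene("g", "chr2", "+", 400, 900)]) == []

    def test_signed_distance_is_strand_adjusted(self):
        p = Peak.from_coords("chr1", 99_500, 100_500, "p")  # center 100,000
        genes = [
            gene("downstream_plus", "chr1", "+", 150_000, 151_000),  # tss 150,000
            gene("downstream_minus", "chr1", "-", 40_000, 50_000),  # tss 49,999
        ]
        pairs = dict((g, d) for _, g, d in candidate_pairs([p], genes))
        assert pairs["downstream_plus"] == 50_000  # peak 5' of + gene
        assert pairs["downstream_minus"] == 50_001  # peak 5' of - gene too

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(21)
        peaks = [
            Peak.from_coords("c1", s := int(rng.integers(0, 2_000_000)), s + 400, f"p{i}")
            for i in range(50)
        ]
        genes = [
            gene(f"g{i}", "c1", "+" if rng.random() < 0.5 else "-",
                 s := int(rng.integers(0, 2_000_000)), s + 1000)
            for i in range(50)
        ]
        got = set((p, g) for p, g, _ in candidate_pairs(peaks, genes, window=300_000))
        expected = set(
            (p.id, g.id)
            for p in peaks
            for g in genes
            if abs(g.tss - p.center) <= 300_000
        )
        assert got == expected


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == 1.0 and p == 0.0
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == -1.0

    def test_ties_use_average_ranks(self):
        # hand oracle: average-rank y = (1.5, 1.5, 3.5, 3.5), Pearson of ranks
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([1, 1, 2, 2, 3.0])
        rho, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + (rng.integers(0, 3) - 1) * x
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_exact_permutation_p_small_n(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        rho, p_exact = spearman(x, y, method="exact")
        # oracle: enumerate permutations with scipy's rank correlation
        count = 0
        import itertools

        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / 120)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(y, x)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
        r3, _ = spearman(np.exp(x), y)  # strictly monotone transform
        assert r1 == pytest.approx(r3)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_hand_evaluated_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_with_p_order(self):
        rng = np.random.default_rng(17)
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 400)))
            q = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, ref, atol=1e-12)


def _study_links(link_study):
    atlas = build_atlas(
        link_study.atlas.per_sample_peaks, link_study.atlas.sheet, mode="reproducible"
    )
    atlas.attach_counts(link_study.atlas.counts)
    pairs = candidate_pairs(atlas.peaks, link_study.genes)
    return build_link_map(atlas.ppkm, link_study.tpm, pairs)


class TestBuildLinkMap:
    def test_planted_links_recovered_with_correct_sign(self, link_study):
        links, _ = _study_links(link_study)
        sig = {(l.peak_id, l.gene_id): l for l in links if l.significant}
        truth = {(p, g): s for p, g, s, _ in link_study.truth.true_links}
        for key, sign in truth.items():
            assert key in sig, f"planted link {key} not significant"
            assert sig[key].sign == sign

    def test_alpha_zero_yields_no_significant_links(self, link_study):
        atlas = build_atlas(
            link_study.atlas.per_sample_peaks, link_study.atlas.sheet, mode="reproducible"
        )
        atlas.attach_counts(link_study.atlas.counts)
        pairs = candidate_pairs(atlas.peaks, link_study.genes)
        links, _ = build_link_map(atlas.ppkm, link_study.tpm, pairs, alpha=0.0)
        assert not any(l.significant for l in links)

    def test_degenerate_pairs_skipped_and_counted(self):
        ppkm = IntensityMatrix(
            pd.DataFrame(
                [[1.0, 2, 3, 4, 5, 6], [2.0, 2, 2, 2, 2, 2]],
                index=["pk1", "pk_const"],
                columns=[f"s{i}" for i in range(6)],
            ),
            "ppkm",
        )
        tpm = IntensityMatrix(
            pd.DataFrame([[3.0, 1, 4, 1, 5, 9]], index=["g"], columns=[f"s{i}" for i in range(6)]),
            "tpm",
        )
        pairs = [("pk1", "g", 0), ("pk_const", "g", 0)]
        links, degenerate = build_link_map(ppkm, tpm, pairs)
        assert degenerate == 1
        assert [l.peak_id for l in links] == ["pk1"]

    def test_column_mismatch_rejected(self):
        a = IntensityMatrix(pd.DataFrame([[1.0]], index=["p"], columns=["s1"]), "ppkm")
        b = IntensityMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["s2"]), "tpm")
        with pytest.raises(ValueError):
            build_link_map(a, b, [])


def _mk_link(peak, gene, rho, q, sig=True, dist=0):
    return PeakGeneLink(
        peak_id=peak, gene_id=gene, distance=dist, rho=rho,
        p=q / 2, q=q, significant=sig, sign="positive" if rho > 0 else "negative",
    )


class TestSignProfiles:
    def test_positive_only_and_mixed(self):
        links = [
            _mk_link("pk1", "g1", 0.8, 1e-5),
            _mk_link("pk1", "g2", 0.5, 1e-4),
            _mk_link("pk2", "g1", 0.8, 1e-5),
            _mk_link("pk2", "g3", -0.6, 1e-3),
        ]
        profiles, assoc_frac, peak_frac = classify_sign_profiles(links)
        labels = {p.peak_id: p.label for p in profiles}
        assert labels == {"pk1": "positive_only", "pk2": "mixed"}
        assert assoc_frac == {"positive_only": 0.5, "negative_only": 0.0, "mixed": 0.5}
        assert sum(assoc_frac.values()) == pytest.approx(1.0)
        assert sum(peak_frac.values()) == pytest.approx(1.0)

    def test_insignificant_links_ignored(self):
        links = [_mk_link("pk", "g1", 0.9, 1e-5), _mk_link("pk", "g2", -0.9, 0.5, sig=False)]
        profiles, _, _ = classify_sign_profiles(links)
        assert profiles[0].label == "positive_only"


class TestLinkSummary:
    def test_genes_per_peak(self):
        links = [_mk_link("pk", f"g{i}", 0.7, 1e-4, dist=i * 1000) for i in range(3)]
        out = link_summary(links)
        assert out["per_sign"]["positive"]["genes_per_peak"] == 3.0
        assert out["per_sign"]["positive"]["n_links"] == 3
        assert out["per_sign"]["negative"]["n_links"] == 0

    def test_empty_input_no_crash(self):
        out = link_summary([])
        assert out["per_sign"]["positive"]["genes_per_peak"] is None

    def test_matches_group_by(self):
        rng = np.random.default_rng(33)
        links = []
        for i in range(200):
            links.append(
                _mk_link(
                    f"pk{rng.integers(0, 20)}", f"g{rng.integers(0, 30)}",
                    float(rng.uniform(-1, 1) or 0.1), 1e-4,
                    dist=int(rng.integers(-400_000, 400_000)),
                )
            )
        out = link_summary(links)
        df = pd.DataFrame([(l.peak_id, l.gene_id, l.sign) for l in links],
                          columns=["peak", "gene", "sign"]).drop_duplicates()
        for sign in ("positive", "negative"):
            sub = df[df["sign"] == sign]
            expected = sub.groupby("peak")["gene"].nunique().mean()
            assert out["per_sign"][sign]["genes_per_peak"] == pytest.approx(expected)
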