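"""Atlas building, PPKM/TPM identities, peak annotation and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from pigatlas.intervals import GeneModel, GenomicInterval, Peak, merge_intervals, overlap_length
from pigatlas.quantify import (
    IntensityMatrix,
    SampleSheet,
    annotate_genomic_category,
    build_atlas,
    classify_proximal_distal,
    cluster_samples,
    filter_expressed,
    frip,
    ppkm_normalize,
    tpm_normalize,
)


def peak(chrom, start, end, pid=None):
    return Peak.from_coords(chrom, start, end, pid)


def sheet_2tissue():
    return SampleSheet.from_records(
        [("t1_r1", "t1", 1), ("t1_r2", "t1", 2), ("t2_r1", "t2", 1), ("t2_r2", "t2", 2)]
    )


def matrix(values, rows, cols, kind="counts"):
    return IntensityMatrix(pd.DataFrame(values, index=rows, columns=cols), kind)


class TestSampleSheet:
    def test_duplicate_tissue_replicate_rejected(self):
        with pytest.raises(ValueError, match="tissue, replicate"):
            SampleSheet.from_records([("a", "t1", 1), ("b", "t1", 1)])

    def test_lookup(self):
        sheet = sheet_2tissue()
        assert sheet.tissues == ["t1", "t2"]
        assert sheet.samples_of("t2") == ["t2_r1", "t2_r2"]
        assert sheet.tissue_of("t1_r2") == "t1"


class TestBuildAtlas:
    def test_reproducible_keeps_replicate_backed_peak(self):
        per_sample = {
            "t1_r1": [peak("chr1", 100, 200)],
            "t1_r2": [peak("chr1", 150, 250)],
            "t2_r1": [],
            "t2_r2": [],
        }
        atlas = build_atlas(per_sample, sheet_2tissue(), mode="reproducible")
        assert [(p.start, p.end) for p in atlas.peaks] == [(100, 250)]
        assert atlas.support[atlas.peaks[0].id] == {"t1_r1", "t1_r2"}

    def test_single_replicate_peak_dropped_in_reproducible_kept_in_union(self):
        per_sample = {
            "t1_r1": [peak("chr1", 100, 200)],
            "t1_r2": [],
            "t2_r1": [],
            "t2_r2": [],
        }
        union = build_atlas(per_sample, sheet_2tissue(), mode="union")
        repro = build_atlas(per_sample, sheet_2tissue(), mode="reproducible")
        assert len(union.peaks) == 1
        assert len(repro.peaks) == 0

    def test_min_samples_counts_distinct_samples(self):
        per_sample = {
            "t1_r1": [peak("chr1", 100, 200)],
            "t1_r2": [peak("chr1", 180, 260)],
            "t2_r1": [peak("chr1", 240, 300)],
            "t2_r2": [peak("chr2", 0, 50)],
        }
        atlas3 = build_atlas(per_sample, sheet_2tissue(), mode="min_samples", min_samples=3)
        assert [(p.chrom, p.start, p.end) for p in atlas3.peaks] == [("chr1", 100, 300)]
        atlas1 = build_atlas(per_sample, sheet_2tissue(), mode="min_samples", min_samples=1)
        assert len(atlas1.peaks) == 2

    def test_unknown_mode_and_bad_k(self):
        with pytest.raises(ValueError):
            build_atlas({}, sheet_2tissue(), mode="bogus")
        with pytest.raises(ValueError):
            build_atlas({}, sheet_2tissue(), mode="min_samples", min_samples=0)

    def test_reproducible_matches_brute_force(self):
        rng = np.random.default_rng(5)
        sheet = SampleSheet.from_records(
            [(f"t{t}_r{r}", f"t{t}", r) for t in (1, 2, 3) for r in (1, 2)]
        )
        per_sample = {}
        for sid in sheet.sample_ids:
            peaks = []
            for _ in range(40):
                s = int(rng.integers(0, 9_500))
                peaks.append(peak("chrA", s, s + int(rng.integers(50, 400))))
            per_sample[sid] = peaks
        atlas = build_atlas(per_sample, sheet, mode="reproducible")

        # brute force: per tissue, merged segments of the union overlapped by
        # every replicate, then merged across tissues
        survivors = []
        for t in ("t1", "t2", "t3"):
            reps = [f"{t}_r1", f"{t}_r2"]
            merged = merge_intervals([p.interval for r in reps for p in per_sample[r]])
            for seg in merged:
                if all(
                    any(overlap_length(seg, p.interval) > 0 for p in per_sample[r])
                    for r in reps
                ):
                    survivors.append(seg)
        expected = merge_intervals(survivors)
        assert [p.interval for p in atlas.peaks] == expected

    def test_reproducible_covered_bases_subset_of_union(self, default_study):
        per_sample = default_study.atlas.per_sample_peaks
        sheet = default_study.atlas.sheet
        union = build_atlas(per_sample, sheet, mode="union")
        repro = build_atlas(per_sample, sheet, mode="reproducible")
        union_ivs = sorted(p.interval for p in union.peaks)
        for p in repro.peaks:
            assert any(
                u.chrom == p.chrom and u.start <= p.start and p.end <= u.end
                for u in union_ivs
            )


class TestPpkm:
    def test_single_peak_single_sample(self):
        m = matrix([[10]], ["p1"], ["s1"])
        out = ppkm_normalize(m, {"p1": 1000})
        assert out.df.iloc[0, 0] == pytest.approx(1_000_000)

    def test_two_peaks_hand_computed(self):
        m = matrix([[30], [70]], ["p1", "p2"], ["s1"])
        out = ppkm_normalize(m, {"p1": 1000, "p2": 2000})
        assert out.df["s1"].tolist() == pytest.approx([300_000, 350_000])

    def test_zero_count_cell_gives_zero(self):
        m = matrix([[0, 5], [10, 5]], ["p1", "p2"], ["s1", "s2"])
        out = ppkm_normalize(m, {"p1": 100, "p2": 100})
        assert out.df.loc["p1", "s1"] == 0

    def test_all_zero_column_names_sample(self):
        m = matrix([[0, 1]], ["p1"], ["bad_sample", "ok"])
        with pytest.raises(ValueError, match="bad_sample"):
            ppkm_normalize(m, {"p1": 100})

    def test_column_identity_and_depth_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n, m = int(rng.integers(2, 40)), int(rng.integers(2, 8))
            counts = rng.integers(0, 1000, size=(n, m))
            counts[0] += 1  # no all-zero column
            lengths = {f"p{i}": int(rng.integers(100, 2000)) for i in range(n)}
            mat = matrix(counts, [f"p{i}" for i in range(n)], [f"s{j}" for j in range(m)])
            out = ppkm_normalize(mat, lengths)
            len_kb = np.array([lengths[f"p{i}"] for i in range(n)]) / 1e3
            colsum = out.df.to_numpy() * len_kb[:, None]
            assert np.allclose(colsum.sum(axis=0), 1e6, rtol=1e-6)
            # scaling one sample's counts leaves its PPKM column unchanged
            scaled = counts.copy()
            scaled[:, 0] *= 7
            out2 = ppkm_normalize(
                matrix(scaled, [f"p{i}" for i in range(n)], [f"s{j}" for j in range(m)]),
                lengths,
            )
            assert np.allclose(out.df.iloc[:, 0], out2.df.iloc[:, 0])


class TestTpm:
    def test_single_gene_is_million(self):
        out = tpm_normalize(matrix([[7]], ["g1"], ["s1"]), {"g1": 500})
        assert out.df.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_counts_different_lengths(self):
        out = tpm_normalize(matrix([[10], [10]], ["g1", "g2"], ["s1"]), {"g1": 1000, "g2": 2000})
        assert out.df["s1"].tolist() == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 500, size=(30, 5))
        counts[0] += 1
        out = tpm_normalize(
            matrix(counts, [f"g{i}" for i in range(30)], [f"s{j}" for j in range(5)]),
            {f"g{i}": int(rng.integers(200, 5000)) for i in range(30)},
        )
        assert np.allclose(out.df.sum(axis=0), 1e6, rtol=1e-6)


class TestFilterExpressed:
    def _tpm(self, row, n=40):
        return matrix([row], ["g"], [f"s{i}" for i in range(n)], kind="tpm")

    def test_more_than_two_is_strict(self):
        row = [1.0, 1.0] + [0.0] * 38
        assert filter_expressed(self._tpm(row), 0.0, 2, strict_support=True) == []
        row3 = [1.0, 1.0, 1.0] + [0.0] * 37
        assert filter_expressed(self._tpm(row3), 0.0, 2, strict_support=True) == ["g"]

    def test_fraction_uses_ceiling(self):
        # 8 of 71 samples with TPM > 1: ceil(0.10 * 71) = 8 -> kept
        row = [2.0] * 8 + [0.5] * 63
        assert filter_expressed(self._tpm(row, n=71), 1.0, 0.10) == ["g"]
        row7 = [2.0] * 7 + [0.5] * 64
        assert filter_expressed(self._tpm(row7, n=71), 1.0, 0.10) == []

    def test_all_zero_gene_always_dropped(self):
        row = [0.0] * 40
        assert filter_expressed(self._tpm(row), 0.0, 1) == []

    def test_threshold_comparison_is_strict(self):
        row = [1.0] * 40  # exactly at min_tpm, never counted
        assert filter_expressed(self._tpm(row), 1.0, 1) == []


def simple_genes():
    return [
        GeneModel(
            id="gA", chrom="chr1", strand="+", start=10_000, end=13_000,
            features=(
                ("UTR5", GenomicInterval("chr1", 10_000, 10_200)),
                ("CDS", GenomicInterval("chr1", 10_200, 12_800)),
                ("UTR3", GenomicInterval("chr1", 12_800, 13_000)),
                ("exon", GenomicInterval("chr1", 10_000, 13_000)),
            ),
        ),
        GeneModel(
            id="gB", chrom="chr1", strand="-", start=50_000, end=56_000,
            features=(
                ("exon", GenomicInterval("chr1", 50_000, 51_000)),
                ("exon", GenomicInterval("chr1", 55_000, 56_000)),
                ("CDS", GenomicInterval("chr1", 50_500, 51_000)),
            ),
        ),
    ]


class TestProximalDistal:
    def test_boundary_inclusive_at_threshold(self):
        genes = simple_genes()  # gA TSS at 10,000
        peaks = [peak("chr1", 8_800, 9_201, "at1000"), peak("chr1", 8_799, 9_200, "at1001")]
        assert peaks[0].center == 9_000 and peaks[1].center == 8_999
        labels = classify_proximal_distal(peaks, genes, threshold=1000)
        assert labels["at1000"] == "proximal"
        assert labels["at1001"] == "distal"

    def test_partition_is_exhaustive(self, default_study, default_atlas):
        labels = classify_proximal_distal(default_atlas.peaks, default_study.genes)
        n_prox = sum(1 for v in labels.values() if v == "proximal")
        n_dist = sum(1 for v in labels.values() if v == "distal")
        assert n_prox + n_dist == len(default_atlas.peaks)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            classify_proximal_distal([peak("chr1", 0, 100)], [])


class TestGenomicCategory:
    def test_precedence_and_labels(self):
        genes = simple_genes()
        peaks = [
            peak("chr1", 11_000, 11_100, "in_cds"),
            peak("chr1", 10_050, 10_150, "in_utr5"),
            peak("chr1", 12_850, 12_950, "in_utr3"),
            peak("chr1", 52_000, 52_100, "in_intron"),  # inside gB span, no exon
            peak("chr1", 30_000, 30_100, "between"),
        ]
        labels, fractions = annotate_genomic_category(peaks, genes)
        assert labels == {
            "in_cds": "CDS",
            "in_utr5": "UTR5",
            "in_utr3": "UTR3",
            "in_intron": "intron",
            "between": "intergenic",
        }
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_fractions_match_brute_force_tally(self, default_study, default_atlas):
        peaks = default_atlas.peaks[:100]
        labels, fractions100 = annotate_genomic_category(peaks, default_study.genes)
        tally = {}
        for lab in labels.values():
            tally[lab] = tally.get(lab, 0) + 1
        for cat, frac in fractions100.items():
            assert frac == pytest.approx(tally.get(cat, 0) / 100)


class TestFrip:
    def test_examples(self):
        out = frip({"a": 5000, "b": 0, "c": 7}, {"a": 20000, "b": 10, "c": 7})
        assert out == {"a": 0.25, "b": 0.0, "c": 1.0}

    def test_total_below_in_peak_rejected(self):
        with pytest.raises(ValueError, match="x"):
            frip({"x": 10}, {"x": 5})


class TestClusterSamples:
    def test_identical_columns_merge_at_zero(self):
        m = matrix([[1, 1], [5, 5]], ["p1", "p2"], ["a", "b"], kind="ppkm")
        nwk = cluster_samples(m)
        assert nwk == "(a:0,b:0):0;"

    def test_two_samples_newick_has_two_leaves(self):
        m = matrix([[1, 9], [5, 2]], ["p1", "p2"], ["s1", "s2"], kind="ppkm")
        nwk = cluster_samples(m)
        assert "s1" in nwk and "s2" in nwk and nwk.endswith(";")

    def test_fewer_than_two_columns_rejected(self):
        m = matrix([[1], [5]], ["p1", "p2"], ["only"], kind="ppkm")
        with pytest.raises(ValueError):
            cluster_samples(m)

    def test_replicates_cluster_as_siblings(self, default_atlas):
        # rebuild the linkage the same way to check sibling structure
        values = np.log2(default_atlas.ppkm.df.to_numpy() + 1.0)
        linkage = hierarchy.linkage(values.T, method="ward")
        cols = default_atlas.ppkm.col_ids
        n = len(cols)
        # first merges of the dendrogram should pair replicates of a tissue
        partner = {}
        for a, b, _, _ in linkage:
            if a < n and b < n:
                partner[cols[int(a)]] = cols[int(b)]
                partner[cols[int(b)]] = cols[int(a)]
        for sid, mate in partner.items():
            assert sid.split("_")[0] == mate.split("_")[0]
        # and the newick output contains every sample exactly once
        nwk = cluster_samples(default_atlas.ppkm)
        for sid in cols:
            assert nwk.count(sid) == 1
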