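import numpy as np
import pytest

from tftf.dataset_builder import (
    CohortSpec,
    augment,
    build_ansr,
    build_cohort,
    positive_windows,
    sample_negatives,
)
from tftf.genomic_io import GenomicInterval, Peak

CHROM = {"chr1": 10_000}


def pk(start, end, cell="c1", chrom="chr1", enr=0.0):
    return Peak(GenomicInterval(chrom, start, end), enr, cell)


class TestPositiveWindows:
    def test_center_rule(self):
        (iv, cell, _), = positive_windows([pk(100, 200)], CHROM)
        assert (iv.start, iv.end) == (100, 201)  # center 150, start 150 - 50

    def test_length_one_peak_centered(self):
        (iv, _, _), = positive_windows([pk(5000, 5001)], CHROM)
        assert iv.start == 5000 - 50 and iv.length == 101

    def test_identical_peaks_two_cells_one_region_two_samples(self):
        out = positive_windows([pk(100, 200, "a"), pk(100, 200, "b")], CHROM)
        assert len(out) == 2
        assert out[0][0] == out[1][0]  # same unioned window
        assert {c for _, c, _ in out} == {"a", "b"}

    def test_duplicate_within_cell_unioned(self):
        out = positive_windows([pk(100, 200, "a"), pk(100, 200, "a")], CHROM)
        assert len(out) == 1

    def test_edge_window_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = positive_windows([pk(0, 2), pk(500, 600)], CHROM)
        assert len(out) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            positive_windows([], CHROM)


class TestNegativeSampling:
    MARKED = [GenomicInterval("chr1", 4000, 4101)]

    def legal_starts(self):
        # brute-force enumeration of all legal 101-bp starts
        legal = []
        for s in range(0, 10_000 - 101 + 1):
            w = (s, s + 101)
            if w[1] <= 4000 - 2000 or w[0] >= 4101 + 2000:
                legal.append(s)
        return set(legal)

    def test_margin_respected_exhaustive(self):
        legal = self.legal_starts()
        ivs = sample_negatives(CHROM, self.MARKED, 200, margin=2000, seed=1)
        assert len(ivs) == 200
        for iv in ivs:
            assert iv.start in legal
            assert iv.length == 101
        # the derived bounds: [0, 1899] U [6101, 9899]
        assert legal == set(range(0, 1900)) | set(range(6101, 9900))

    def test_zero_requested(self):
        assert sample_negatives(CHROM, self.MARKED, 0) == []

    def test_deterministic_given_seed(self):
        a = sample_negatives(CHROM, self.MARKED, 50, seed=9)
        b = sample_negatives(CHROM, self.MARKED, 50, seed=9)
        assert a == b

    def test_distinct_starts(self):
        ivs = sample_negatives(CHROM, self.MARKED, 300, seed=0)
        assert len({iv.start for iv in ivs}) == 300

    def test_insufficient_space_reports_achievable(self):
        with pytest.raises(ValueError, match=r"\d+ eligible"):
            sample_negatives(CHROM, self.MARKED, 10_000, margin=2000)


class TestANSR:
    def test_exact_overlap_excluded(self):
        out = build_ansr([pk(100, 201, "train")], [pk(100, 201, "test")], CHROM)
        assert out == []

    def test_disjoint_included(self):
        out = build_ansr([pk(100, 201, "train")], [pk(5000, 5101, "test")], CHROM)
        assert len(out) == 1

    def test_disjoint_from_test_positives(self):
        train = [pk(100, 201, "a"), pk(3000, 3101, "a"), pk(7000, 7101, "a")]
        test = [pk(3000, 3101, "t")]
        ansr = build_ansr(train, test, CHROM)
        test_windows = {iv for iv, _, _ in positive_windows(test, CHROM)}
        assert not any(a.overlaps(t) for a in ansr for t in test_windows)


class TestAugmentation:
    def test_fifteen_windows_with_expected_starts(self):
        ivs = augment(pk(100, 200), 10_000)
        starts = sorted(iv.start for iv in ivs)
        assert starts == list(range(93, 108))  # 100 +- 7
        assert len(ivs) == 15
        assert all(iv.length == 101 for iv in ivs)

    def test_fourteen_extra_per_peak(self):
        ivs = augment(pk(100, 200), 10_000)
        assert len(ivs) - 1 == 14

    def test_cohort_grows_fifteen_fold(self):
        peaks = [pk(s, s + 100) for s in range(1000, 9000, 500)]
        total = sum(len(augment(p, 10_000)) for p in peaks)
        assert total == 15 * len(peaks)

    def test_off_edge_shifts_dropped(self):
        with pytest.warns(UserWarning):
            ivs = augment(pk(48, 52), 10_000)  # center 50, start 0; -i goes negative
        assert len(ivs) == 8  # original + 7 right shifts

    def test_all_windows_cover_source_center(self):
        p = pk(100, 200)
        center = 150
        for iv in augment(p, 10_000):
            assert iv.start <= center < iv.end


class TestCohort:
    def make_world(self):
        from tftf.genomic_io import SignalTrack
        from tftf.synthetic import WorldConfig, generate

        return generate(
            WorldConfig(genome_length=50_000, n_cell_types=3, n_sites=6,
                        n_decoys=2, p_bind=0.7, min_gap=900, seed=3)
        )

    def test_counts_and_balance(self):
        w = self.make_world()
        spec = CohortSpec(train_cells=["cell0", "cell1"], test_cell="cell2",
                          margin=500, seed=0)
        ch = build_cohort(w.genome, w.peaks_by_cell, w.tracks, spec)
        counts = ch.manifest["counts"]
        assert counts["train_neg"] == counts["train_pos"]  # exact class balance
        assert counts["test_neg"] == counts["test_pos"]
        for s in ch.train:
            assert len(s.seq) == 101 and len(s.signals[0]) == 101

    def test_negative_signal_comes_from_training_cell(self):
        w = self.make_world()
        spec = CohortSpec(train_cells=["cell0", "cell1"], test_cell="cell2",
                          margin=500, seed=0)
        ch = build_cohort(w.genome, w.peaks_by_cell, w.tracks, spec)
        negs = [s for s in ch.train if s.cohort == "train_neg"]
        assert all(s.cell_id in {"cell0", "cell1"} for s in negs)

    def test_ansr_samples_use_test_cell_signal(self):
        w = self.make_world()
        spec = CohortSpec(train_cells=["cell0", "cell1"], test_cell="cell2",
                          margin=500, seed=0)
        ch = build_cohort(w.genome, w.peaks_by_cell, w.tracks, spec)
        for s in ch.ansr:
            assert s.cell_id == "cell2" and s.label == "negative"
            expected = w.tracks["cell2"]["h3k4me3"].query(s.interval.start, s.interval.end)
            assert np.array_equal(s.signals[0], expected)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(train_cells=["a"], test_cell="b", margin=-1)
        with pytest.raises(ValueError):
            CohortSpec(train_cells=["a"], test_cell="b", neg_ratio=0)
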