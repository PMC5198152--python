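"""Peak-table processing: windowing, denoising, consolidation, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflp.profiles import (Peak, PeakTable, TRFMatrix, bin_across_samples,
                            consolidate_replicates, denoise, filter_minor_trfs,
                            size_filter)


def table(sizes_areas, sample="S1", rep=1, enzyme="HaeIII"):
    return PeakTable(sample, rep, enzyme,
                     [Peak(s, a) for s, a in sizes_areas])


class TestSizeFilter:
    def test_boundaries_inclusive(self):
        t = table([(49.6, 1), (50.0, 1), (312.4, 1), (500.0, 1), (503.1, 1)])
        assert [p.size_bp for p in size_filter(t).peaks] == [50.0, 312.4, 500.0]

    def test_empty_table(self):
        assert size_filter(table([])).peaks == []

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            size_filter(table([(100, 1)]), min_bp=500, max_bp=50)

    def test_matches_bruteforce(self, rng):
        sizes = rng.uniform(10, 600, size=1000)
        t = table([(s, 1.0) for s in sizes])
        kept = {p.size_bp for p in size_filter(t).peaks}
        assert kept == {s for s in sizes if 50 <= s <= 500}


class TestDenoise:
    def test_removes_trace_peaks_keeps_signal(self):
        t = table([(100, 1000), (200, 900), (300, 5), (310, 4), (320, 3)])
        out = denoise(t)
        assert [p.area for p in out.peaks] == [1000, 900]

    def test_single_peak_is_signal(self):
        out = denoise(table([(100, 42)]))
        assert len(out.peaks) == 1

    def test_uniform_table_passes_through(self):
        # no peak below the seed floor -> no noise-floor estimate -> no-op
        t = table([(100, 10), (200, 10), (300, 10), (400, 10)])
        assert len(denoise(t).peaks) == 4

    def test_all_zero_areas_error(self):
        with pytest.raises(ValueError, match="zero"):
            denoise(table([(100, 0.0), (200, 0.0)]))

    def test_idempotent(self, rng):
        for _ in range(20):
            n_sig = int(rng.integers(3, 10))
            sig = [(float(s), float(a)) for s, a in
                   zip(rng.uniform(60, 490, n_sig), rng.uniform(500, 5000, n_sig))]
            noise = [(float(s), float(a)) for s, a in
                     zip(rng.uniform(50, 500, 25), rng.uniform(0.01, 8.0, 25))]
            once = denoise(table(sig + noise))
            twice = denoise(once)
            assert [(p.size_bp, p.area) for p in twice.peaks] == \
                [(p.size_bp, p.area) for p in once.peaks]

    def test_order_invariant(self, rng):
        peaks = [(100.0, 1000.0), (200.0, 900.0), (300.0, 2.0), (310.0, 1.5),
                 (320.0, 1.0), (330.0, 0.5)]
        ref = {(p.size_bp, p.area) for p in denoise(table(peaks)).peaks}
        for _ in range(5):
            perm = [peaks[i] for i in rng.permutation(len(peaks))]
            got = {(p.size_bp, p.area) for p in denoise(table(perm)).peaks}
            assert got == ref

    def test_never_removes_reportable_peak(self, rng):
        # peaks at >= 1% of total area are immune by construction
        for _ in range(20):
            areas = np.concatenate([rng.uniform(100, 1000, 8),
                                    rng.uniform(0.001, 1.0, 30)])
            t = table([(float(60 + i), float(a)) for i, a in enumerate(areas)])
            kept = {p.area for p in denoise(t).peaks}
            total = areas.sum()
            for a in areas:
                if a / total >= 0.01:
                    assert a in kept


class TestConsolidate:
    def test_consensus_mean_of_three(self):
        reps = [table([(175.1, 10)], rep=1), table([(175.3, 12)], rep=2),
                table([(174.9, 11)], rep=3)]
        out = consolidate_replicates(reps)
        assert len(out.peaks) == 1
        assert out.peaks[0].size_bp == pytest.approx(175.1)
        assert out.peaks[0].area == pytest.approx(11.0)

    def test_minority_peak_dropped(self):
        reps = [table([(175.0, 10), (300.0, 5)], rep=1),
                table([(175.2, 10)], rep=2), table([(174.8, 10)], rep=3)]
        out = consolidate_replicates(reps)
        assert [round(p.size_bp) for p in out.peaks] == [175]

    def test_two_replicates_both_present(self):
        reps = [table([(200.0, 8)], rep=1), table([(200.4, 10)], rep=2)]
        assert len(consolidate_replicates(reps).peaks) == 1

    def test_mixed_samples_error(self):
        with pytest.raises(ValueError, match="mixed"):
            consolidate_replicates([table([(100, 1)], sample="A"),
                                    table([(100, 1)], sample="B", rep=2)])

    def test_adjacent_fragment_groups_not_merged(self):
        # a 175/176 pair present in all three replicates stays two peaks
        reps = [table([(175.0 + d, 10), (176.0 + d, 20)], rep=i + 1)
                for i, d in enumerate((-0.1, 0.0, 0.1))]
        out = consolidate_replicates(reps)
        assert [round(p.size_bp) for p in out.peaks] == [175, 176]
        assert [p.area for p in out.peaks] == [10, 20]


class TestBinning:
    def test_cross_sample_weighted_mean_center(self):
        tables = [table([(455.2, 1)], sample="A", rep=0),
                  table([(456.8, 1)], sample="B", rep=0)]
        m = bin_across_samples(tables)
        assert m.trf_bins == [456]

    def test_same_sample_peaks_stay_separate(self):
        tables = [table([(455.2, 1), (456.8, 1)], sample="A", rep=0)]
        m = bin_across_samples(tables)
        assert len(m.trf_bins) == 2

    def test_disjoint_sizes_identity_binning(self):
        tables = [table([(100.0, 2), (200.0, 2)], sample="A", rep=0),
                  table([(300.0, 5)], sample="B", rep=0)]
        m = bin_across_samples(tables)
        assert m.trf_bins == [100, 200, 300]
        np.testing.assert_allclose(m.abundance.sum(axis=1), 1.0)

    def test_tolerance_to_zero_one_bin_per_size(self, rng):
        sizes = np.round(rng.uniform(60, 490, 30), 0)
        tables = [table([(float(s), 1.0) for s in np.unique(sizes)],
                        sample=f"S{i}", rep=0) for i in range(3)]
        m = bin_across_samples(tables, tolerance_bp=1e-9)
        assert len(m.trf_bins) == len(np.unique(sizes))

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            bin_across_samples([table([(100, 1)], rep=0)], tolerance_bp=0)


class TestMinorFilter:
    def matrix(self, data, bins):
        data = np.asarray(data, dtype=float)
        data = data / data.sum(axis=1, keepdims=True)
        return TRFMatrix("HaeIII", [f"S{i}" for i in range(len(data))],
                         bins, data)

    def test_sub_threshold_bin_removed_boundary_kept(self):
        m = self.matrix([[0.009, 0.991], [0.005, 0.995]], [100, 200])
        out, discarded = filter_minor_trfs(m)
        assert out.trf_bins == [200]
        assert discarded["S0"] == pytest.approx(0.009)
        m2 = self.matrix([[0.01, 0.99]], [100, 200])
        out2, _ = filter_minor_trfs(m2)
        assert out2.trf_bins == [100, 200]

    def test_rows_renormalized(self):
        m = self.matrix([[0.009, 0.5, 0.491]], [100, 200, 300])
        out, _ = filter_minor_trfs(m)
        np.testing.assert_allclose(out.abundance.sum(axis=1), 1.0, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.full(20, 0.3), size=10)
        m = self.matrix(raw, list(range(100, 500, 20)))
        out, _ = filter_minor_trfs(m)
        expect = [b for j, b in enumerate(m.trf_bins)
                  if max(m.abundance[i, j] for i in range(10)) >= 0.01]
        assert out.trf_bins == expect


def test_trf_matrix_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        TRFMatrix("HaeIII", ["A"], [200, 100], np.array([[0.5, 0.5]]))
    with pytest.raises(ValueError, match="sum to 1"):
        TRFMatrix("HaeIII", ["A"], [100, 200], np.array([[0.5, 0.4]]))
    m = TRFMatrix("HaeIII", ["A", "B"], [100, 200],
                  np.array([[0.5, 0.5], [0.0, 0.0]]))  # empty sample allowed
    assert m.abundance.shape == (2, 2)
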