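import numpy as np
import pandas as pd
import pytest

from hapfunnel.summits import (
    MasterSummitList,
    SummitCall,
    SummitRegion,
    count_reads,
    filter_in_master_peaks,
    merge_summits,
    normalize_counts,
    reproducibility_filter,
)


def _calls(pos_pileups, chrom="chr1"):
    return [SummitCall(chrom, p, h) for p, h in pos_pileups]


def greedy_oracle(pos_pileups, radius=250):
    """Independent consolidation oracle: repeatedly take the globally highest
    pileup and discard every remaining summit whose region would overlap it."""
    remaining = sorted(pos_pileups, key=lambda t: (-t[1], t[0]))
    kept = []
    while remaining:
        pos, pileup = remaining.pop(0)
        kept.append((pos, pileup))
        remaining = [
            (p, h) for p, h in remaining
            if not (max(0, p - radius) < pos + radius and max(0, pos - radius) < p + radius)
        ]
    return sorted(kept)


class TestMergeSummits:
    def test_distant_summits_both_kept(self):
        out = merge_summits(_calls([(1000, 10), (1600, 5)]))
        assert len(out) == 2

    def test_overlap_keeps_higher_pileup(self):
        out = merge_summits(_calls([(1000, 10), (1100, 5)]))
        assert len(out) == 1
        assert out[0].summit_pos == 1000 and out[0].pileup == 10

    def test_chain_matches_greedy_oracle(self):
        pts = [(1000, 1), (1200, 9), (1400, 2), (1600, 8), (1800, 3)]
        out = merge_summits(_calls(pts))
        assert sorted((r.summit_pos, r.pileup) for r in out) == greedy_oracle(pts)

    def test_random_instances_match_oracle_nonoverlapping_idempotent(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 40))
            pts = list(zip(
                (rng.choice(5000, size=n, replace=False) * 3).tolist(),
                np.round(rng.uniform(0.1, 100, size=n), 3).tolist(),
            ))
            out = merge_summits(_calls(pts))
            assert sorted((r.summit_pos, r.pileup) for r in out) == greedy_oracle(pts)
            for a, b in zip(out, out[1:]):
                assert a.end <= b.start  # pairwise non-overlapping
            again = merge_summits([SummitCall(r.chrom, r.summit_pos, r.pileup) for r in out])
            assert [(r.summit_pos, r.pileup) for r in again] == [
                (r.summit_pos, r.pileup) for r in out
            ]

    def test_negative_pileup_rejected(self):
        with pytest.raises(ValueError, match="pileup"):
            SummitCall("chr1", 100, -1.0)


class TestMasterPeakFilter:
    def test_summit_inside_peak_kept_outside_removed(self):
        regions = merge_summits(_calls([(1000, 10), (5000, 8)]))
        kept = filter_in_master_peaks(regions, [("chr1", 900, 1400)])
        assert [r.summit_pos for r in kept] == [1000]

    def test_random_regions_match_allpairs_oracle(self, rng):
        regions = merge_summits(_calls([(int(p), 1 + i) for i, p in
                                        enumerate(rng.choice(20000, 10, replace=False))]))
        peaks = [("chr1", 2000, 4000), ("chr1", 9000, 9500), ("chr1", 15000, 18000)]
        kept = filter_in_master_peaks(regions, peaks)
        expected = [r for r in regions
                    if any(s <= r.summit_pos < e for _, s, e in peaks)]
        assert [r.summit_pos for r in kept] == [r.summit_pos for r in expected]


class TestReproducibility:
    def _master(self):
        return MasterSummitList(merge_summits(_calls([(1000, 5), (5000, 7)])))

    def _peaks(self, n_supporting, pos=1000):
        peaks = {f"C{i:02d}": [("chr1", pos - 100, pos + 100)] for i in range(n_supporting)}
        for i in range(n_supporting, 11):
            peaks[f"C{i:02d}"] = [("chr1", 90_000, 90_200)]
        return peaks

    def test_three_supporters_retained(self):
        out = reproducibility_filter(self._master(), self._peaks(3))
        assert [r.summit_pos for r in out.regions] == [1000]
        assert len(out.support[out.regions[0].region_id]) == 3

    def test_two_supporters_removed(self):
        out = reproducibility_filter(self._master(), self._peaks(2))
        assert len(out) == 0

    def test_min_children_one_keeps_any_supported(self):
        out = reproducibility_filter(self._master(), self._peaks(1), min_children=1)
        assert [r.summit_pos for r in out.regions] == [1000]

    def test_monotone_in_threshold(self, rng):
        master = MasterSummitList(merge_summits(
            _calls([(int(p), i + 1.0) for i, p in enumerate(range(1000, 30000, 1500))])
        ))
        peaks = {}
        for i in range(11):
            hits = rng.choice(master.regions, size=int(rng.integers(0, 8)), replace=False)
            peaks[f"C{i:02d}"] = [("chr1", r.start, r.end) for r in hits]
        prev = None
        for k in range(1, 7):
            ids = {r.region_id for r in reproducibility_filter(master, peaks, k).regions}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_threshold_above_children_errors(self):
        with pytest.raises(ValueError, match="min_children"):
            reproducibility_filter(self._master(), self._peaks(3), min_children=12)


class TestCountReads:
    def _master(self):
        return MasterSummitList(merge_summits(_calls([(1000, 5)])))

    def test_inside_and_outside(self):
        frags = {"A": [("chr1", 900, "+"), ("chr1", 1000, "+"), ("chr1", 1249, "-"),
                       ("chr1", 5000, "+")]}
        m = count_reads(frags, self._master())
        assert m.values["A"].sum() == 3

    def test_halfopen_end_not_counted(self):
        master = self._master()
        end = master.regions[0].end
        m = count_reads({"A": [("chr1", end, "+"), ("chr1", end - 1, "+")]}, master)
        assert m.values["A"].iloc[0] == 1

    def test_tn5_shift(self):
        master = self._master()
        # 746 + 4 = 750 (inside); 1255 - 5 = 1250 (outside, half-open end)
        m = count_reads({"A": [("chr1", 746, "+"), ("chr1", 1255, "-")]}, master,
                        apply_shift=True)
        assert m.values["A"].iloc[0] == 1

    def test_random_reads_match_naive_membership(self, rng):
        master = MasterSummitList(merge_summits(
            _calls([(int(p), i + 1.0) for i, p in enumerate(range(500, 20000, 1900))])
        ))
        reads = [("chr1", int(p), "+") for p in rng.integers(0, 21000, size=1000)]
        m = count_reads({"A": reads}, master)
        for r in master.regions:
            naive = sum(1 for _, p, _ in reads if r.start <= p < r.end)
            assert m.values.at[r.region_id, "A"] == naive
        assert m.values["A"].sum() <= len(reads)  # read conservation

    def test_unknown_chrom_warns_and_skips(self):
        with pytest.warns(UserWarning, match="chr9"):
            m = count_reads({"A": [("chr9", 1000, "+")]}, self._master())
        assert m.values["A"].sum() == 0


class TestNormalize:
    def _matrix(self, counts, ids=None):
        ids = ids or [f"s{i}" for i in range(len(counts))]
        values = pd.DataFrame(counts, index=pd.Index(ids, name="region_id"),
                              columns=["A", "B"][: np.shape(counts)[1]])
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": range(0, 1000 * len(ids), 1000),
             "end": range(500, 500 + 1000 * len(ids), 1000),
             "summit_pos": range(250, 250 + 1000 * len(ids), 1000)},
            index=values.index,
        )
        return __import__("hapfunnel.summits", fromlist=["SummitCountMatrix"]).SummitCountMatrix(
            values=values, regions=regions
        )

    def test_depth_scaling_equalizes_proportional_libraries(self):
        m = self._matrix(np.array([[10, 20], [30, 60], [60, 120]]))
        out = normalize_counts(m)
        pd.testing.assert_series_equal(out.values["A"], out.values["B"], check_names=False)
        assert out.normalized

    def test_no_gc_equals_pure_depth_scaling(self):
        m = self._matrix(np.array([[10, 5], [30, 15]]))
        out = normalize_counts(m)
        expected = np.log2(m.values / m.values.sum(axis=0) * 1e6 + 1)
        np.testing.assert_allclose(out.values.to_numpy(), expected.to_numpy())

    def test_planted_gc_trend_removed(self, rng):
        n = 300
        gc = pd.Series(rng.uniform(0.3, 0.7, size=n), index=[f"s{i}" for i in range(n)])
        log2_signal = 5 + 2.0 * gc.to_numpy() + rng.normal(0, 0.1, size=n)
        counts = np.round(np.exp2(log2_signal)).astype(int)
        m = self._matrix(np.column_stack([counts, counts]), ids=list(gc.index))
        out = normalize_counts(m, gc=gc)
        slope = np.polyfit(gc.to_numpy(), out.values["A"].to_numpy(), 1)[0]
        assert abs(slope) < 0.05

    def test_zero_total_child_errors(self):
        m = self._matrix(np.array([[0, 5], [0, 15]]))
        with pytest.raises(ValueError, match="zero reads"):
            normalize_counts(m)

    def test_raw_matrix_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            self._matrix(np.array([[-1, 5]]))
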