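"""CBS segmentation and amplified/unaltered/deleted classification."""

import numpy as np
import pandas as pd
import pytest

from gsvdcna import pattern_analysis as pa
from gsvdcna.errors import DataMismatchError

from conftest import make_bins, make_multi_bins


def _brute_force_max_t(x, min_width):
    """Independent exhaustive search over all circular arc splits."""
    n = x.size
    var = x.var()
    S = np.concatenate(([0.0], np.cumsum(x)))
    best = (-np.inf, None, None)
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            k = j - i
            if k > n - min_width:
                continue
            m1 = (S[j] - S[i]) / k
            m2 = (S[-1] - S[j] + S[i]) / (n - k)
            t = abs(m1 - m2) / np.sqrt(var * (1.0 / k + 1.0 / (n - k)))
            if t > best[0]:
                best = (t, i, j)
    return best


class TestCbsSegment:
    def test_flat_series_one_segment_per_chromosome(self):
        bins = make_multi_bins({"1": 100, "2": 100})
        pattern = pa.CopyNumberPattern(np.zeros(200), bins)
        segs = pa.cbs_segment(pattern, seed=0)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"1", "2"}

    def test_step_breakpoint_recovered_and_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        x = np.where(np.arange(100) >= 50, 1.0, 0.0) + rng.normal(0, 0.05, 100)
        pattern = pa.CopyNumberPattern(x, make_bins(100))
        segs = pa.cbs_segment(pattern, seed=0)
        boundaries = sorted(s.start // 1000 for s in segs)[1:]
        assert len(boundaries) == 1 and abs(boundaries[0] - 50) <= 1
        # the first split must equal the exhaustive max-t search
        t, i, j = _brute_force_max_t(x, 3)
        found = pa._max_t_split(x, 3)
        assert (found[0], found[1]) == (i, j)
        assert found[2] == pytest.approx(t, rel=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        x = np.where(np.arange(80) >= 30, 0.8, 0.0) + rng.normal(0, 0.1, 80)
        bins = make_bins(80)
        a = pa.cbs_segment(pa.CopyNumberPattern(x, bins), seed=1)
        b = pa.cbs_segment(pa.CopyNumberPattern(x + 5.0, bins), seed=1)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 150) + np.where(np.arange(150) >= 70, 3.0, 0.0)
        bins = make_bins(150)
        a = pa.cbs_segment(pa.CopyNumberPattern(x, bins), seed=9)
        b = pa.cbs_segment(pa.CopyNumberPattern(x, bins), seed=9)
        assert [(s.start, s.end, s.mean_value) for s in a] == [
            (s.start, s.end, s.mean_value) for s in b
        ]

    def test_short_chromosome_single_segment_with_warning(self):
        bins = make_bins(4)
        with pytest.warns(UserWarning, match="single segment"):
            segs = pa.cbs_segment(pa.CopyNumberPattern(np.array([0, 5, 0, 5.0]), bins))
        assert len(segs) == 1 and segs[0].n_bins == 4


class TestClassifySegments:
    def _crafted_pattern(self):
        # 4000 autosomal bins, all at +-0.1: reference mean 0, bin SD exactly 0.1
        values = np.empty(4000)
        values[:3950] = np.tile([0.1, -0.1], 1975)
        values[3950:3975] = 0.1  # the segment under test: 25 bins at +0.1
        values[3975:4000] = -0.1  # its mirror image
        return pa.CopyNumberPattern(values, make_bins(4000))

    def test_z_is_five_for_hand_example_and_mirrored_deletion(self):
        pattern = self._crafted_pattern()
        segs = [
            pa.SegmentCall("1", 3950 * 1000, 3975 * 1000, 25, 0.1),
            pa.SegmentCall("1", 3975 * 1000, 4000 * 1000, 25, -0.1),
        ]
        out = pa.classify_segments(segs, pattern, z_threshold=2.0)
        assert out[0].z_score == pytest.approx(5.0, rel=1e-12)
        assert out[0].call == "amplified"
        assert out[1].z_score == pytest.approx(-5.0, rel=1e-12)
        assert out[1].call == "deleted"

    def test_zero_z_is_unaltered(self):
        pattern = self._crafted_pattern()
        seg = pa.SegmentCall("1", 0, 2000 * 1000, 2000, 0.0)
        out = pa.classify_segments([seg], pattern)
        assert out[0].call == "unaltered" and out[0].z_score == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescaling_leaves_z_unchanged(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.2, 500)
        bins = make_bins(500)
        seg = [pa.SegmentCall("1", 100 * 1000, 140 * 1000, 40, float(values[100:140].mean()))]
        z1 = pa.classify_segments(seg, pa.CopyNumberPattern(values, bins))[0].z_score
        scaled = 3.0 * values + 7.0
        seg2 = [pa.SegmentCall("1", 100 * 1000, 140 * 1000, 40, float(scaled[100:140].mean()))]
        z2 = pa.classify_segments(seg2, pa.CopyNumberPattern(scaled, bins))[0].z_score
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_per_chromosome_reference(self):
        bins = make_multi_bins({"1": 100, "2": 100})
        values = np.concatenate([np.tile([0.1, -0.1], 50), np.tile([1.1, 0.9], 50)])
        seg = [pa.SegmentCall("2", 0, 100 * 1000, 100, 1.0)]
        out = pa.classify_segments(seg, pa.CopyNumberPattern(values, bins), reference="per_chromosome")
        assert out[0].call == "unaltered"  # chr2 runs at mean 1.0 itself

    def test_x_excluded_from_autosome_reference(self):
        bins = make_multi_bins({"1": 100, "X": 100})
        values = np.concatenate([np.tile([0.1, -0.1], 50), np.full(100, -0.5)])
        seg = [pa.SegmentCall("X", 0, 100 * 1000, 100, -0.5)]
        out = pa.classify_segments(seg, pa.CopyNumberPattern(values, bins))
        assert out[0].call == "deleted"


class TestComparePatterns:
    def _calls(self, spec):
        # spec: list of (call, mean)
        return [
            pa.SegmentCall("1", i * 1000, (i + 1) * 1000, 1, mean, 0.0, call)
            for i, (call, mean) in enumerate(spec)
        ]

    def test_self_comparison_is_perfect(self):
        a = self._calls([("amplified", 0.5), ("unaltered", 0.0), ("deleted", -0.4)])
        summary = pa.compare_patterns(a, a)
        assert summary["agreement_fraction"] == 1.0
        assert summary["bounded_fraction"] == 1.0
        assert summary["a_subset_of_b"]

    def test_subset_relation(self):
        a = self._calls([("amplified", 0.3), ("deleted", -0.3), ("unaltered", 0.0)])
        b = self._calls([("amplified", 0.5), ("deleted", -0.5), ("amplified", 0.4)])
        summary = pa.compare_patterns(a, b)
        assert summary["a_subset_of_b"]
        assert summary["bounded_fraction"] == 1.0
        assert summary["altered_a"] == 2 and summary["altered_b"] == 3

    def test_bounding_fails_on_sign_flip_or_magnitude(self):
        a = self._calls([("amplified", 0.5), ("deleted", -0.5)])
        b = self._calls([("deleted", -0.5), ("deleted", -0.2)])
        summary = pa.compare_patterns(a, b)
        assert not summary["a_subset_of_b"]
        assert summary["bounded_fraction"] == 0.0

    def test_coordinate_mismatch_rejected(self):
        a = self._calls([("amplified", 0.5)])
        b = [pa.SegmentCall("2", 0, 1000, 1, 0.5, 0.0, "amplified")]
        with pytest.raises(DataMismatchError):
            pa.compare_patterns(a, b)


class TestClassifyOverSegmentList:
    def test_flat_pattern_is_unaltered(self):
        pattern = pa.CopyNumberPattern(np.tile([0.01, -0.01], 100), make_bins(200))
        ext = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [200 * 1000]})
        out = pa.classify_over_segment_list(pattern, ext)
        assert len(out) == 1 and out[0].call == "unaltered"

    def test_planted_amplification_found(self):
        values = np.tile([0.05, -0.05], 200)
        values[100:140] += 1.0
        pattern = pa.CopyNumberPattern(values, make_bins(400))
        ext = pd.DataFrame({"chrom": ["1"], "start": [100 * 1000], "end": [140 * 1000]})
        out = pa.classify_over_segment_list(pattern, ext)
        assert out[0].call == "amplified" and out[0].n_bins == 40

    def test_empty_list_gives_empty_output(self):
        pattern = pa.CopyNumberPattern(np.zeros(10), make_bins(10))
        out = pa.classify_over_segment_list(pattern, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert out == []

    def test_out_of_range_segment_clipped_with_warning(self):
        pattern = pa.CopyNumberPattern(np.tile([0.1, -0.1], 50), make_bins(100))
        ext = pd.DataFrame({"chrom": ["1"], "start": [50 * 1000], "end": [500 * 1000]})
        with pytest.warns(UserWarning, match="clipped"):
            out = pa.classify_over_segment_list(pattern, ext)
        assert out[0].end == 100 * 1000 and out[0].n_bins == 50

    def test_round_trip_tsv(self, tmp_path):
        segs = [pa.SegmentCall("1", 0, 5000, 5, 0.3, 2.5, "amplified")]
        pa.segments_to_tsv(segs, tmp_path / "segs.tsv")
        df = pd.read_csv(tmp_path / "segs.tsv", sep="\t")
        assert df.loc[0, "call"] == "amplified" and df.loc[0, "n_bins"] == 5
        ext = pa.read_segment_list(tmp_path / "segs.tsv")
        assert list(ext.columns) == ["chrom", "start", "end"]
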