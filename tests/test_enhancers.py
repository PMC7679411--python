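"""Dependency calling from paired coverage, direct targets, and the rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crest.contrasts import classify
from crest.enhancers import (
    call_direct_targets,
    call_enhancers,
    classify_dependency,
    dependency_log2_ratio,
    mann_whitney,
    merge_tracks_mean,
    normalize_track,
)
from crest.genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomicInterval,
    IntervalSet,
)


def mw_enumeration_p(a, b):
    """Exact two-sided p by enumerating all group assignments (no ties)."""
    pooled = sorted(list(a) + list(b))
    n_a = len(a)
    obs = sum(1 for x in a for y in b if x > y)
    n_ab = n_a * len(b)
    count = 0
    total = 0
    for positions in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in positions]
        ys = [pooled[i] for i in range(len(pooled)) if i not in positions]
        u = sum(1 for x in xs for y in ys if x > y)
        total += 1
        if min(u, n_ab - u) <= min(obs, n_ab - obs):
            count += 1
    return count / total


class TestNormalize:
    def test_scales_to_target(self):
        t = CoverageTrack([("chr1", 0, 100, 4.0)])
        out = normalize_track(t, 100.0)
        assert out.total_signal() == pytest.approx(100.0, rel=1e-9)
        assert list(out.steps())[0][3] == pytest.approx(1.0)

    def test_already_at_target_unchanged(self):
        t = CoverageTrack([("chr1", 0, 10, 2.0)])
        assert list(normalize_track(t, 20.0).steps()) == list(t.steps())

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_track(CoverageTrack(), 1.0)


class TestMergeTracksMean:
    def test_piecewise_mean_with_implicit_zeros(self):
        t1 = CoverageTrack([("chr1", 0, 10, 2.0)])
        t2 = CoverageTrack([("chr1", 5, 15, 4.0)])
        merged = merge_tracks_mean([t1, t2])
        assert list(merged.steps()) == [
            ("chr1", 0, 5, 1.0),
            ("chr1", 5, 10, 3.0),
            ("chr1", 10, 15, 2.0),
        ]
        assert merged.total_signal() == pytest.approx((t1.total_signal() + t2.total_signal()) / 2)


class TestLog2Ratio:
    def test_halving_is_minus_one(self):
        assert dependency_log2_ratio(100, 50, 0.001) == pytest.approx(-1.0, abs=1e-4)

    def test_equal_signals_zero(self):
        assert dependency_log2_ratio(37.5, 37.5) == 0.0

    def test_zero_coverage_stabilized(self):
        assert dependency_log2_ratio(0, 0, 1.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dependency_log2_ratio(-1, 5)

    @pytest.mark.parametrize(
        "ratio,expected", [(-1.0, True), (0.0, False), (-0.5, False), (-0.5000001, True)]
    )
    def test_threshold_is_strict(self, ratio, expected):
        assert classify_dependency(ratio, -0.5) is expected


class TestCallEnhancers:
    def toy(self):
        """Three TF-bound peaks; knockdown quarters the first two."""
        peaks = IntervalSet(
            [GenomicInterval("chr1", s, s + 100) for s in (0, 1000, 2000)]
        )
        tf = IntervalSet([GenomicInterval("chr1", s + 40, s + 60) for s in (0, 1000, 2000)])
        control = CoverageTrack([("chr1", s, s + 100, 10.0) for s in (0, 1000, 2000)])
        kd = CoverageTrack(
            [("chr1", 0, 100, 2.5), ("chr1", 1000, 1100, 2.5), ("chr1", 2000, 2100, 10.0)]
        )
        return peaks, tf, control, kd

    def test_two_of_three_dependent(self):
        peaks, tf, control, kd = self.toy()
        total = control.total_signal()  # 3000; kd totals 1500 -> scaled x2
        res = call_enhancers(peaks, tf, normalize_track(control, total),
                             normalize_track(kd, total), pseudocount=0.001)
        # depth normalization doubles the knockdown track: quartered peaks end
        # at ratio 0.5 (log2 = -1), the untouched peak at ratio 2 (log2 = +1)
        assert len(res.calls) == 3
        assert res.calls[0].log2_ratio == pytest.approx(-1.0, abs=1e-4)
        assert res.calls[2].log2_ratio == pytest.approx(1.0, abs=1e-4)
        assert [c.is_dependent for c in res.calls] == [True, True, False]
        assert res.dependent_fraction == pytest.approx(2 / 3)

    def test_identical_tracks_nothing_dependent(self):
        peaks, tf, control, _ = self.toy()
        res = call_enhancers(peaks, tf, control, control)
        assert res.n_dependent == 0

    def test_no_overlap_gives_empty_output(self):
        peaks, _, control, kd = self.toy()
        tf_far = IntervalSet([GenomicInterval("chr1", 5000, 5100)])
        res = call_enhancers(peaks, tf_far, control, control)
        assert res.calls == []

    def test_unnormalized_tracks_rejected(self):
        peaks, tf, control, kd = self.toy()
        with pytest.raises(ValueError, match="normalized"):
            call_enhancers(peaks, tf, control, kd)

    def test_joint_rescaling_invariance(self):
        peaks, tf, control, kd = self.toy()
        total = control.total_signal()
        base = call_enhancers(peaks, tf, normalize_track(control, 1e6),
                              normalize_track(kd, 1e6))
        scaled = call_enhancers(
            peaks, tf,
            normalize_track(control.scaled(7.3), 1e6),
            normalize_track(kd.scaled(7.3), 1e6),
        )
        for c1, c2 in zip(base.calls, scaled.calls):
            assert c1.log2_ratio == pytest.approx(c2.log2_ratio, abs=1e-9)
            assert c1.is_dependent == c2.is_dependent

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_dependency_monotone_in_knockdown_signal(self, control, k1, k2):
        lo, hi = sorted((k1, k2))
        r_lo = dependency_log2_ratio(control, lo)
        r_hi = dependency_log2_ratio(control, hi)
        assert r_lo <= r_hi
        # decreasing kd can only turn independent -> dependent
        if classify_dependency(r_hi):
            assert classify_dependency(r_lo)


class TestDirectTargets:
    def setup_toy(self, dependent=True):
        genes = [
            GeneAnnotation("NOTCH3", "chr1", 50_000),
            GeneAnnotation("FARGENE", "chr1", 900_000),
        ]
        classes = classify({"NOTCH3", "FARGENE"}, set())
        peak = GenomicInterval("chr1", 39_500, 40_500)  # ~10 kb upstream
        tf = IntervalSet([GenomicInterval("chr1", 39_900, 40_100)])
        from crest.enhancers import DependencyCall

        call = DependencyCall(
            peak=peak, control_signal=100.0, kd_signal=40.0,
            log2_ratio=-1.3 if dependent else 0.0, is_dependent=dependent,
        )
        return genes, classes, [call], tf

    def test_notch3_like_configuration_is_direct(self):
        genes, classes, calls, tf = self.setup_toy(dependent=True)
        out = {t.gene_id: t for t in call_direct_targets(genes, classes, calls, tf)}
        assert out["NOTCH3"].is_direct and out["NOTCH3"].gene_class == "specific"
        assert not out["FARGENE"].is_direct  # no peak, no TF within window

    def test_non_dependent_peak_is_not_direct(self):
        genes, classes, calls, tf = self.setup_toy(dependent=False)
        out = {t.gene_id: t for t in call_direct_targets(genes, classes, calls, tf)}
        assert out["NOTCH3"].tf_bound and not out["NOTCH3"].is_direct

    def test_missing_annotation_raises_with_gene_name(self):
        genes, classes, calls, tf = self.setup_toy()
        with pytest.raises(KeyError, match="FARGENE"):
            call_direct_targets(genes[:1], classes, calls, tf)


class TestMannWhitney:
    def test_small_exact_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_symmetric(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u_statistic == pytest.approx(8.0)  # n^2 / 2 with mid-ranks
        assert res.p_value >= 0.99

    def test_extreme_separation(self):
        res = mann_whitney(list(range(1, 9)), list(range(101, 109)))
        assert res.p_value < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for n_a, n_b in [(2, 2), (3, 4), (5, 5), (7, 6)]:
            vals = rng.permutation(100)[: n_a + n_b].astype(float)
            a, b = vals[:n_a], vals[n_a:]
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(mw_enumeration_p(a, b), abs=1e-12)
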