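"""Fiber measurements: initiation events, velocity, IOD, figure classes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oritime import combing as cb
from oritime import synth as sy


def fiber(segs, length=None, fid="f"):
    segments = tuple(sy.FiberSegment(lbl, a, b) for lbl, a, b in segs)
    if length is None:
        length = max((s.end for s in segments), default=10.0) + 10.0
    return sy.Fiber(fiber_id=fid, length=length, segments=segments)


def fiberset(*fibers_, **kw):
    return sy.FiberSet(fibers=tuple(fibers_), **kw)


class TestInitiationEvents:
    def test_idu_core_flanked_by_cldu(self):
        f = fiber([("CldU", 0, 30), ("IdU", 30, 60), ("CldU", 60, 90)])
        assert cb.find_initiation_events(f) == [45.0]

    def test_single_cldu_track_is_not_an_origin(self):
        f = fiber([("CldU", 10, 40)])
        assert cb.find_initiation_events(f) == []

    def test_gapped_idu_core_within_limit(self):
        f = fiber([("CldU", 0, 20), ("IdU", 20, 28), ("IdU", 32, 40),
                   ("CldU", 40, 60)])
        assert cb.find_initiation_events(f) == [30.0]
        # beyond the linking limit the two forks are independent
        far = fiber([("CldU", 0, 20), ("IdU", 20, 28), ("IdU", 60, 68),
                     ("CldU", 68, 88)])
        assert cb.find_initiation_events(far) == []

    def test_divergent_cldu_pair(self):
        f = fiber([("CldU", 0, 30), ("CldU", 31, 61)])
        assert cb.find_initiation_events(f) == [30.5]

    def test_simulated_events_near_true_origins(self):
        cfg = sy.SimulationConfig(
            seed=13, chrom_length=2_000_000, firing_spread_minutes=0.0,
            fiber_length_mean=50_000.0, measurement_noise_kb=0.0, n_fibers=1,
        )
        origins = (
            sy.Origin(position=600_000, timing_class="early", firing_time=0.0),
            sy.Origin(position=1_400_000, timing_class="early", firing_time=0.0),
        )
        genome = sy.GenomeModel("chrS", 2_000_000, origins, 1.5, {"on": 1.0})
        fibers = sy.make_fibers(genome, "on", cfg)
        events = cb.find_initiation_events(next(iter(fibers)))
        assert len(events) == 2
        assert events[0] == pytest.approx(600.0, abs=cfg.detection_threshold)
        assert events[1] == pytest.approx(1400.0, abs=cfg.detection_threshold)


class TestForkVelocity:
    @pytest.mark.parametrize("length,expected", [(30.0, 1.0), (45.0, 1.5)])
    def test_cldu_length_over_pulse2(self, length, expected):
        f = fiber([("IdU", 10, 20), ("CldU", 20, 20 + length)],
                  length=20 + length + 10)
        out = cb.fork_velocity(fiberset(f))
        assert len(out) == 1
        assert out[0].velocity == pytest.approx(expected)

    def test_exclusions(self):
        lone = fiber([("CldU", 10, 40)])                      # newborn: skip
        merged = fiber([("IdU", 0, 10), ("CldU", 10, 40),
                        ("IdU", 40, 50)], length=60)          # fused: skip
        truncated = fiber([("IdU", 10, 20), ("CldU", 20, 50)],
                          length=50)                          # runs off end
        assert cb.fork_velocity(fiberset(lone, merged, truncated)) == []

    def test_simulation_recovers_fork_speed(self, combing_scenario):
        cfg, _, control, _ = combing_scenario
        vels = [m.velocity for m in cb.fork_velocity(control)]
        assert len(vels) >= 200
        median = float(np.median(vels[:200]))
        assert abs(median - cfg.fork_speed) / cfg.fork_speed < 0.10


class TestInterOriginDistances:
    def test_consecutive_event_distance(self):
        f = fiber([("CldU", 20, 40), ("IdU", 40, 60), ("CldU", 60, 80),
                   ("CldU", 120, 140), ("IdU", 140, 160), ("CldU", 160, 180)],
                  length=220)
        iods = cb.inter_origin_distances(fiberset(f))
        assert len(iods) == 1
        assert iods[0].distance == pytest.approx(100.0)

    def test_single_event_gives_no_iod(self):
        f = fiber([("CldU", 0, 30), ("IdU", 30, 60), ("CldU", 60, 90)])
        assert cb.inter_origin_distances(fiberset(f)) == []

    def test_long_iod_count(self):
        iods = [cb.IodMeasurement("f", d) for d in (50.0, 310.0, 400.0)]
        assert cb.count_long_iods(iods) == 2

    def test_low_firing_increases_iod(self, combing_scenario):
        _, _, control, knockdown = combing_scenario
        dc = [m.distance for m in cb.inter_origin_distances(control)]
        dk = [m.distance for m in cb.inter_origin_distances(knockdown)]
        assert min(len(dc), len(dk)) >= 100
        _, p = cb.mann_whitney(dc[:100], dk[:100])
        assert p < 0.05
        assert np.median(dk) > np.median(dc)


class TestClassifyFigures:
    def test_rule_table(self):
        cases = {
            "isolated_fork": fiber([("IdU", 10, 20), ("CldU", 20, 50)],
                                   length=70),
            "one_origin_bidirectional": fiber(
                [("CldU", 10, 40), ("IdU", 40, 70), ("CldU", 70, 100)],
                length=120),
            "single_origin_only": fiber(
                [("CldU", 0, 30), ("IdU", 30, 60), ("CldU", 60, 90)],
                length=90),
            "interspersed_origins": fiber(
                [("CldU", 10, 30), ("IdU", 30, 50), ("CldU", 50, 70),
                 ("CldU", 110, 130), ("IdU", 130, 150), ("CldU", 150, 170)],
                length=200),
            "termination": fiber(
                [("IdU", 10, 30), ("CldU", 30, 70), ("IdU", 70, 90)],
                length=110),
        }
        for expected, f in cases.items():
            counts = cb.classify_figures(fiberset(f))
            assert counts.counts[expected] == 1, (expected, counts.counts)
            assert counts.n_total == 1

    def test_counts_exhaustive_on_simulated_set(self, combing_scenario):
        _, _, control, _ = combing_scenario
        counts = cb.classify_figures(control)
        assert counts.n_total == sum(counts.counts.values())
        assert counts.n_total > 200
        assert all(v >= 0 for v in counts.counts.values())

    def test_low_firing_shifts_figure_mix(self, combing_scenario):
        _, _, control, knockdown = combing_scenario
        cc = cb.classify_figures(control)
        ck = cb.classify_figures(knockdown)
        _, _, p = cb.chi_square_counts(cc, ck)
        assert p < 0.01
        assert ck.proportion("interspersed_origins") < \
            cc.proportion("interspersed_origins")


class TestBoxSummary:
    def test_examples(self):
        s = cb.box_summary(range(1, 11))
        assert s.median == pytest.approx(5.5)
        const = cb.box_summary([4.0] * 9)
        assert const.p10 == const.median == const.p90 == 4.0
        assert const.outliers == ()
        with pytest.raises(ValueError):
            cb.box_summary([])

    def test_matches_sort_and_interpolate_oracle(self):
        # independent type-7 oracle: h = (n-1)q, linear interpolation
        def oracle(xs, q):
            xs = sorted(xs)
            h = (len(xs) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        rng = np.random.default_rng(99)
        for _ in range(200):
            xs = rng.normal(size=rng.integers(1, 50)).tolist()
            s = cb.box_summary(xs)
            assert s.p10 == pytest.approx(oracle(xs, 0.10), rel=1e-12, abs=1e-12)
            assert s.median == pytest.approx(oracle(xs, 0.50), rel=1e-12, abs=1e-12)
            assert s.p90 == pytest.approx(oracle(xs, 0.90), rel=1e-12, abs=1e-12)
            assert all(x < s.p10 or x > s.p90 for x in s.outliers)


def exact_u_pvalue(a, b):
    """Full-enumeration two-sided Mann-Whitney p (no ties), tiny samples."""
    pooled = sorted(a) + sorted(b)
    na = len(a)
    obs_u = sum(1 for x in a for y in b if x > y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for x in xs for y in ys if x > y))
    us = np.array(us)
    lo = np.mean(us <= obs_u)
    hi = np.mean(us >= obs_u)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_multisets(self):
        u, p = cb.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p >= 0.99
        u, p = cb.mann_whitney([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_disjoint_small_samples_exact(self):
        u, p = cb.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(1, 15))
        b = rng.normal(size=rng.integers(1, 15))
        ua, _ = cb.mann_whitney(a, b)
        ub, _ = cb.mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for na, nb in [(3, 3), (4, 3), (4, 4), (5, 4)]:
            a = rng.normal(size=na).tolist()
            b = rng.normal(size=nb).tolist()
            _, p = cb.mann_whitney(a, b)
            assert p == pytest.approx(exact_u_pvalue(a, b), rel=1e-9)


class TestChiSquare:
    def test_identical_counts(self):
        x2, df, p = cb.chi_square_counts([10, 20, 30], [10, 20, 30])
        assert x2 == 0.0 and p == 1.0 and df == 2

    def test_hand_computed_two_by_two(self):
        x2, df, p = cb.chi_square_counts([50, 50], [25, 75])
        assert x2 == pytest.approx(40 / 3)
        assert df == 1
        assert p == pytest.approx(float(stats.chi2.sf(40 / 3, 1)))

    def test_order_invariance(self):
        a, b = [12, 40, 8], [30, 15, 22]
        x2, _, _ = cb.chi_square_counts(a, b)
        x2p, _, _ = cb.chi_square_counts(a[::-1], b[::-1])
        assert x2 == pytest.approx(x2p)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(1, 80, size=5)
            b = rng.integers(1, 80, size=5)
            x2, df, p = cb.chi_square_counts(a, b)
            ref = stats.chi2_contingency(np.vstack([a, b]), correction=False)
            assert x2 == pytest.approx(ref.statistic)
            assert df == ref.dof
            assert p == pytest.approx(ref.pvalue)

    def test_pooled_zero_class_dropped(self):
        with pytest.warns(UserWarning):
            x2, df, p = cb.chi_square_counts([10, 0, 30], [20, 0, 15])
        assert df == 1
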