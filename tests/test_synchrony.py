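"""Overlap statistics, null models, virtual-dyad correction."""

import numpy as np
import pytest

from dyadsync.ethogram import Ethogram, FreezingBout, SessionLayout
from dyadsync.synchrony import (
    DegenerateTraceError,
    Dyad,
    NullConfig,
    SynchronyResult,
    apply_nonsocial_correction,
    chance_overlap,
    corrected_synchrony,
    enumerate_virtual_dyads,
    freezing_probability_trace,
    null_overlap_spread,
    observed_overlap,
    raw_synchrony,
    rotation_overlaps,
)


def brute_force_rotation_overlaps(a, b):
    """Independent O(n^2) oracle: overlap of a against every roll of b."""
    a, b = np.asarray(a), np.asarray(b)
    return np.array(
        [(a & np.roll(b, -k)).sum() / a.size for k in range(a.size)]
    )


class TestOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], 0.25),
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
            ([1, 1, 1, 0, 0], [1, 1, 1, 0, 0], 0.6),
        ],
    )
    def test_observed(self, a, b, expected):
        assert observed_overlap(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], 0.25),
            ([0, 0, 0, 0], [1, 0, 1, 0], 0.0),
            ([1] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], 0.3),
        ],
    )
    def test_chance(self, a, b, expected):
        assert chance_overlap(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            observed_overlap([1, 0], [1, 0, 1])


class TestNullSpread:
    def test_binomial_closed_form(self):
        a = np.tile([1, 0], 240)  # p = 0.5
        b = np.tile([0, 1], 240)
        sd = null_overlap_spread(a, b, method="binomial")
        assert sd == pytest.approx(np.sqrt(0.25 * 0.75 / 480), abs=1e-12)

    def test_degenerate_trace_flagged(self):
        with pytest.raises(DegenerateTraceError):
            null_overlap_spread([1, 1, 1, 1], [1, 0, 1, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exhaustive_rotations_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 65))
        a = (rng.random(n) < 0.4).astype(np.uint8)
        b = (rng.random(n) < 0.6).astype(np.uint8)
        if a.mean() in (0, 1) or b.mean() in (0, 1):
            pytest.skip("degenerate draw")
        oracle = brute_force_rotation_overlaps(a, b)
        fft = rotation_overlaps(a, b)
        assert np.allclose(fft, oracle, atol=1e-12)
        sd = null_overlap_spread(a, b, method="circular_shift", n_surrogates="all")
        assert sd == pytest.approx(oracle[1:].std(), abs=1e-12)

    def test_exhaustive_rotation_mean_identity(self, rng):
        # over ALL n rotations the mean overlap is exactly p_a * p_b, hence
        # the nonzero-rotation mean is (n E - O) / (n - 1)
        a = (rng.random(64) < 0.5).astype(np.uint8)
        b = (rng.random(64) < 0.5).astype(np.uint8)
        ov = rotation_overlaps(a, b)
        e = chance_overlap(a, b)
        assert ov.mean() == pytest.approx(e, abs=1e-12)
        assert ov[1:].mean() == pytest.approx(
            (64 * e - observed_overlap(a, b)) / 63, abs=1e-12
        )

    def test_sampled_spread_close_to_exhaustive(self, rng):
        a = (rng.random(480) < 0.5).astype(np.uint8)
        b = (rng.random(480) < 0.5).astype(np.uint8)
        exact = null_overlap_spread(a, b, n_surrogates="all")
        sampled = null_overlap_spread(a, b, n_surrogates=5000, rng=rng)
        assert sampled == pytest.approx(exact, rel=0.1)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            null_overlap_spread([1, 0] * 8, [0, 1] * 8, n_surrogates=10)


def _dyad_from_traces(a, b, layout=None, ids=("a", "b"), **kwargs):
    """Build a dyad whose CS traces equal the given 0/1 arrays."""
    a, b = np.asarray(a), np.asarray(b)
    layout = layout or SessionLayout(fps=4, pre_cs_s=1, cs_s=len(a) / 4)
    lo = layout.pre_cs_frames

    def bouts(v):
        edges = np.flatnonzero(np.diff(np.r_[0, v, 0]))
        return tuple(
            FreezingBout(int(s) + lo, int(e) + lo)
            for s, e in zip(edges[::2], edges[1::2])
        )

    return Dyad(
        "d1",
        Ethogram(ids[0], layout, bouts(a)),
        Ethogram(ids[1], layout, bouts(b)),
        **kwargs,
    )


class TestRawSynchrony:
    def test_identical_traces_closed_form(self):
        v = np.repeat([1, 0], 240)  # p = 0.5, one long bout
        d = _dyad_from_traces(v, v, ids=("a", "b"))
        r = raw_synchrony(d, NullConfig(method="binomial"))
        expected = 0.25 / np.sqrt(0.25 * 0.75 / 480)
        assert r.raw == pytest.approx(expected)  # ~ 12.65
        assert r.observed == pytest.approx(0.5)
        assert r.chance == pytest.approx(0.25)

    def test_observed_equals_chance_gives_zero(self):
        # two square waves in quadrature: O = E = 0.25 (bouts stay >= 1 s)
        a = np.tile([1, 1, 1, 1, 0, 0, 0, 0], 60)
        b = np.roll(a, 2)
        d = _dyad_from_traces(a, b)
        r = raw_synchrony(d, NullConfig(method="binomial"))
        assert r.raw == pytest.approx(0.0, abs=1e-12)

    def test_anti_aligned_traces_negative(self):
        a = np.tile([1] * 4 + [0] * 4, 60)
        b = np.tile([0] * 4 + [1] * 4, 60)
        d = _dyad_from_traces(a, b)
        assert raw_synchrony(d, NullConfig(method="binomial")).raw < 0
        assert raw_synchrony(d, NullConfig()).raw < 0  # circular-shift null too

    def test_independent_traces_center_on_zero(self, rng):
        # Monte-Carlo null calibration of the standardized score
        raws = []
        for _ in range(500):
            a = (rng.random(480) < 0.5).astype(np.uint8)
            b = (rng.random(480) < 0.5).astype(np.uint8)
            o, e = observed_overlap(a, b), chance_overlap(a, b)
            sd = null_overlap_spread(a, b, method="binomial")
            raws.append((o - e) / sd)
        assert abs(np.mean(raws)) < 3.0 / np.sqrt(500)

    def test_degenerate_dyad_propagates(self):
        d = _dyad_from_traces(np.ones(480, int), np.tile([1, 1, 1, 1, 0, 0, 0, 0], 60))
        with pytest.raises(DegenerateTraceError):
            raw_synchrony(d)


def _toy_group(n_dyads, seed=0, sex="MM"):
    from dyadsync.simulate import SimConfig, simulate_cohort

    dyads, _ = simulate_cohort(
        SimConfig(), n_dyads, seed=seed, sex_composition=sex
    )
    return dyads


class TestVirtualDyads:
    def test_two_real_dyads_give_four_virtual(self):
        virtual = enumerate_virtual_dyads(_toy_group(2))
        assert len(virtual) == 4  # C(4,2) - 2
        assert all(v.is_virtual for v in virtual)

    def test_counts_scale_as_combinations(self):
        # k real same-sex dyads over 2k subjects: C(2k, 2) - k virtual
        for k in (3, 5):
            assert len(enumerate_virtual_dyads(_toy_group(k))) == (
                k * (2 * k - 1) - k
            )

    def test_mf_group_crosses_sexes_only(self):
        virtual = enumerate_virtual_dyads(_toy_group(3, sex="MF"))
        # 3 males x 3 females - 3 real pairs
        assert len(virtual) == 6
        assert all(set(v.member_sexes()) == {"M", "F"} for v in virtual)

    def test_duplicate_subject_rejected(self):
        d = _toy_group(2)
        twin = Dyad(
            "dup",
            d[0].ethogram_a,
            d[1].ethogram_b,
            sex_composition="MM",
        )
        with pytest.raises(ValueError, match="duplicate subject"):
            enumerate_virtual_dyads([d[0], d[1], twin])

    def test_fewer_than_two_dyads_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            enumerate_virtual_dyads(_toy_group(1))


class TestCorrection:
    def _result(self, dyad_id, raw, virtual=False):
        return SynchronyResult(dyad_id, 0.5, 0.5, 0.3, 0.25, 0.02, raw, is_virtual=virtual)

    def test_zero_component_is_identity(self):
        real = [self._result("d1", 2.0)]
        virtual = [self._result("v1", 0.5, True), self._result("v2", -0.5, True)]
        corrected, comp = corrected_synchrony(real, virtual)
        assert comp == pytest.approx(0.0)
        assert corrected[0].corrected == pytest.approx(2.0)

    def test_component_subtraction(self):
        real = [self._result("d1", 2.0)]
        virtual = [self._result("v1", 0.27, True)]
        corrected, comp = corrected_synchrony(real, virtual)
        assert comp == pytest.approx(0.27)
        assert corrected[0].corrected == pytest.approx(1.73)

    def test_virtual_mean_recentered_to_zero(self, rng):
        virtual = [
            self._result(f"v{i}", float(r), True)
            for i, r in enumerate(rng.normal(0.8, 0.4, size=50))
        ]
        _, comp = corrected_synchrony([], virtual)
        recentered = apply_nonsocial_correction(virtual, comp)
        assert np.mean([r.corrected for r in recentered]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_virtual_set_rejected(self):
        with pytest.raises(ValueError, match="no virtual"):
            corrected_synchrony([self._result("d1", 1.0)], [])


class TestFreezingProbabilityTrace:
    def test_constant_traces_stay_flat(self):
        mean, sd = freezing_probability_trace([np.ones(40), np.ones(40)])
        assert np.allclose(mean, 1.0) and np.allclose(sd, 0.0)

    def test_single_trace_matches_moving_average_oracle(self):
        v = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        w = 4
        # direct centered moving average with edge renormalization; an even
        # window leans one frame toward the past: frames [i-w/2, i+w/2-1]
        oracle = np.array(
            [
                v[max(0, i - w // 2) : i + (w - 1) // 2 + 1].mean()
                for i in range(len(v))
            ]
        )
        mean, _ = freezing_probability_trace([v], window_s=1.0, fps=4)
        assert np.allclose(mean, oracle)

    def test_sd_zero_iff_identical(self, rng):
        a = (rng.random(64) < 0.5).astype(float)
        b = (rng.random(64) < 0.5).astype(float)
        _, sd_same = freezing_probability_trace([a, a.copy()])
        _, sd_diff = freezing_probability_trace([a, b])
        assert np.allclose(sd_same, 0.0)
        assert sd_diff.max() > 0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            freezing_probability_trace([])
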