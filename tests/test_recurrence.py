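"""Recurrence point sets, DCRPs, shuffle baselines, turn masking, CORM."""

import numpy as np
import pytest

from dyadcrqa.recurrence import (
    RecurrenceConfigError,
    condition_on_turn,
    corm,
    corm_fast,
    dcrp,
    dcrp_fast,
    lag_counts,
    recurrence_points,
    rr_by_lag,
    shuffle_baseline,
)
from dyadcrqa.series import MASK, OFF

from conftest import make_record, make_series, random_series


def naive_rr_and_corm(x, y, L, B):
    """O(N^2) double-loop reference for rr(d) and banded CORM."""
    xv, yv = list(x.values), list(y.values)
    n = len(xv)
    counts = np.zeros(2 * L + 1, dtype=int)
    band_sum = 0
    band_n = 0
    for i in range(n):
        for j in range(n):
            if xv[i] in (OFF, MASK) or xv[i] != yv[j]:
                continue
            d = j - i
            if abs(d) <= L:
                counts[d + L] += 1
            if abs(d) <= B:
                band_sum += d
                band_n += 1
    rr = counts / (n - np.abs(np.arange(-L, L + 1)))
    c = band_sum / (B * band_n) if band_n else 0.0
    return rr, c


class TestRecurrencePoints:
    def test_hand_enumerated_point_set(self):
        x = make_series(["A", "A", "B", OFF], labels=("A", "B"))
        y = make_series(["A", "B", "B", "B"], labels=("A", "B"))
        rs = recurrence_points(x, y)
        assert rs.as_pairs() == {(0, 0), (1, 0), (2, 1), (2, 2), (2, 3)}

    def test_self_recurrence_contains_diagonal(self):
        x = make_series(["A", "B", "A", "C"], labels=("A", "B", "C"))
        rs = recurrence_points(x, x)
        assert {(i, i) for i in range(4)} <= rs.as_pairs()

    def test_all_off_gives_empty_set(self):
        x = make_series([OFF] * 4, labels=("A",))
        y = make_series(["A"] * 4, labels=("A",))
        assert recurrence_points(x, y).n_points == 0

    def test_off_and_mask_never_match_themselves(self):
        x = make_series([OFF, MASK], labels=("A",))
        assert recurrence_points(x, x).n_points == 0

    def test_length_mismatch_rejected(self):
        x = make_series(["A"], labels=("A",))
        y = make_series(["A", "A"], labels=("A",))
        with pytest.raises(ValueError, match="length"):
            recurrence_points(x, y)


class TestDCRP:
    def test_hand_computed_rates(self):
        x = make_series(["A", "A", "B", OFF], labels=("A", "B"))
        y = make_series(["A", "B", "B", "B"], labels=("A", "B"))
        prof = dcrp(recurrence_points(x, y), L=1, n_bins=3)
        assert prof.rr == pytest.approx([2 / 3, 2 / 4, 1 / 3])

    def test_identical_series_peak_at_zero(self):
        x = make_series(list("ABCABC"), labels=("A", "B", "C"))
        prof = dcrp(recurrence_points(x, x), L=1, n_bins=3)
        assert prof.rr[1] == 1.0
        assert prof.peak_lag() == 0

    def test_default_geometry(self):
        x = random_series(np.random.default_rng(0), 200)
        prof = dcrp(recurrence_points(x, x), L=150, n_bins=43)
        assert len(prof.rr) == 301
        assert prof.n_bins == 43 and prof.bin_width == 7
        assert len(prof.binned_rr) == 43
        assert prof.bin_lags[21] == 0  # central bin holds lag 0

    def test_divisibility_enforced(self):
        x = make_series(list("AB") * 10, labels=("A", "B"))
        with pytest.raises(RecurrenceConfigError, match="divisible"):
            dcrp(recurrence_points(x, x), L=5, n_bins=4)

    def test_fast_path_equals_point_set_path(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            x = random_series(rng, n)
            y = random_series(rng, n)
            L = int(rng.integers(1, n // 2))
            a = dcrp(recurrence_points(x, y), L=L, n_bins=1).rr
            b = rr_by_lag(x.codes(), y.codes(), L)
            assert np.array_equal(a, b)

    def test_antisymmetry_under_swap(self, rng):
        """rr_{X,Y}(d) = rr_{Y,X}(-d) exactly, and CORMs negate."""
        for _ in range(20):
            n = int(rng.integers(8, 50))
            x = random_series(rng, n)
            y = random_series(rng, n)
            L = min(n - 1, 10)
            assert np.array_equal(
                rr_by_lag(x.codes(), y.codes(), L),
                rr_by_lag(y.codes(), x.codes(), L)[::-1])
            cx = corm(recurrence_points(x, y), B=5)
            cy = corm(recurrence_points(y, x), B=5)
            assert cx.value == -cy.value

    def test_rates_bounded(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = random_series(rng, n, p_off=0.4)
            y = random_series(rng, n, p_off=0.4)
            rr = rr_by_lag(x.codes(), y.codes(), min(n - 1, 8))
            assert np.all((rr >= 0) & (rr <= 1))

    def test_peak_lag_tie_breaks_toward_zero_then_negative(self):
        x = make_series(["A", OFF, "A"], labels=("A",))
        p = dcrp(recurrence_points(x, x), L=1, n_bins=3)
        # rr = [0.5, ~0.66, 0.5]: unique max at 0
        assert p.peak_lag() == 0
        y = make_series([OFF, OFF, OFF], labels=("A",))
        p2 = dcrp(recurrence_points(y, y), L=1, n_bins=3)
        # all-zero profile: tie -> lag 0
        assert p2.peak_lag() == 0


class TestShuffleBaseline:
    def test_constant_series_baseline_is_one(self):
        x = make_series(["A"] * 30, labels=("A",))
        base = shuffle_baseline(x, x, L=5, n_bins=11, n_shuffles=5, seed=0)
        assert np.allclose(base.rr, 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = random_series(rng, 200)
        y = random_series(rng, 200)
        a = shuffle_baseline(x, y, L=10, n_bins=21, n_shuffles=10, seed=7)
        b = shuffle_baseline(x, y, L=10, n_bins=21, n_shuffles=10, seed=7)
        assert np.array_equal(a.rr, b.rr)

    def test_lag_coupled_pair_baseline_is_flat(self):
        """Shuffling a strongly lag-coupled pair removes the lag structure."""
        rng = np.random.default_rng(11)
        n = 3000
        xc = rng.integers(9, size=n)
        yc = np.roll(xc, 5)
        x = make_series([chr(65 + c) for c in xc])
        y = make_series([chr(65 + c) for c in yc])
        coupled = dcrp_fast(x, y, L=70, n_bins=47)
        assert coupled.rr.max() == 1.0  # delayed copy
        base = shuffle_baseline(x, y, L=70, n_bins=47, n_shuffles=100, seed=1)
        assert base.binned_rr.max() - base.binned_rr.min() < 0.02


class TestConditionOnTurn:
    def test_masks_other_speakers_samples(self):
        rec = make_record(
            turn_vals=["trained", "trained", "untrained", "untrained"],
            gaze_t=["A", "A", "B", "B"], gaze_u=["A", "B", "B", "A"])
        x, y = condition_on_turn(rec, "trained")
        assert list(x.values) == ["A", "A", MASK, MASK]
        assert list(y.values) == ["A", "B", MASK, MASK]

    def test_zero_turn_speaker_gives_empty_recurrence(self):
        rec = make_record(
            turn_vals=["trained"] * 4,
            gaze_t=["A"] * 4, gaze_u=["A"] * 4)
        x, y = condition_on_turn(rec, "untrained")
        assert all(v == MASK for v in x.values)
        assert recurrence_points(x, y).n_points == 0

    def test_unknown_speaker_rejected(self):
        rec = make_record(["trained"], ["A"], ["A"])
        with pytest.raises(ValueError, match="speaker"):
            condition_on_turn(rec, "listener")

    def test_conditioning_never_adds_recurrence(self, rng):
        """Per-lag counts of the conditioned pair <= the unconditioned pair."""
        for _ in range(10):
            n = 40
            turn = rng.choice(["trained", "untrained"], size=n)
            gaze_t = random_series(rng, n).values
            gaze_u = random_series(rng, n).values
            rec = make_record(list(turn), list(gaze_t), list(gaze_u))
            full = lag_counts(recurrence_points(rec.gaze_trained, rec.gaze_untrained), 10)
            for spk in ("trained", "untrained"):
                x, y = condition_on_turn(rec, spk)
                cond = lag_counts(recurrence_points(x, y), 10)
                assert np.all(cond <= full)


class TestCORM:
    def test_hand_computed_value(self):
        x = make_series(["A", "A", "B", OFF], labels=("A", "B"))
        y = make_series(["A", "B", "B", "B"], labels=("A", "B"))
        res = corm(recurrence_points(x, y), B=3)
        # lags: 0, -1, -1, 0, +1 -> sum -1 over 5 points -> -1/15
        assert res.value == pytest.approx(-1 / 15)
        assert res.n_points == 5

    def test_self_pair_is_symmetric_zero(self):
        x = make_series(list("ABCABCAB"), labels=("A", "B", "C"))
        assert corm(recurrence_points(x, x), B=4).value == 0.0

    def test_delayed_copy_is_positive(self):
        rng = np.random.default_rng(2)
        xc = rng.integers(9, size=3000)
        x = make_series([chr(65 + c) for c in xc])
        y = make_series([chr(65 + c) for c in np.concatenate([np.full(5, -1) % 9, xc[:-5]])])
        # y copies x delayed by 5 samples -> rows (x) lead
        res = corm_fast(x, y, B=40)
        assert res.value > 0

    def test_empty_band_flagged_not_fatal(self):
        x = make_series([OFF, OFF], labels=("A",))
        res = corm(recurrence_points(x, x), B=1)
        assert res.value == 0.0 and res.empty_band

    def test_magnitude_bounded_and_fast_path_agrees(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            x = random_series(rng, n)
            y = random_series(rng, n)
            B = int(rng.integers(1, n))
            a = corm(recurrence_points(x, y), B=B)
            b = corm_fast(x, y, B=B)
            assert abs(a.value) <= 1.0
            assert a.value == pytest.approx(b.value, abs=1e-15)
            assert a.n_points == b.n_points


class TestNaiveOracle:
    def test_engine_matches_double_loop_reference(self, rng):
        """Engine rr(d) and CORM equal an O(N^2) scan bit-exactly."""
        for _ in range(40):
            n = int(rng.integers(5, 51))
            labels = ("A", "B", "C", "D")[: int(rng.integers(1, 5))]
            x = random_series(rng, n, labels=labels, p_off=0.25)
            y = random_series(rng, n, labels=labels, p_off=0.25)
            L = int(rng.integers(1, n))
            B = int(rng.integers(1, n))
            ref_rr, ref_corm = naive_rr_and_corm(x, y, L, B)
            rr = rr_by_lag(x.codes(), y.codes(), L)
            assert np.array_equal(rr, ref_rr)
            assert corm_fast(x, y, B=B).value == ref_corm
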