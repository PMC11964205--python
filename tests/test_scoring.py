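import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tapsync import (
    CONDITIONS,
    ScoringConfig,
    TapEventSeries,
    TapperParams,
    TapTrial,
    bessel_ratio,
    detect_phase,
    detect_tap_interval,
    exclude_wrong_rate,
    generate_stimulus_train,
    logit_transform,
    mean_resultant,
    rayleigh_test,
    remove_pause_taps,
    score_trial,
    simulate_tapper,
    taps_to_angles,
    trim_initial_taps,
)
from tapsync.stimuli import StimulusSequence

ISI = 1 / 2.4


def events_with_itis(itis, start=1.0):
    return TapEventSeries(start + np.concatenate([[0.0], np.cumsum(itis)]))


class TestIntervalDetection:
    def test_double_beat_tapping(self):
        ev = events_with_itis([0.84] * 10)
        assert detect_tap_interval(ev, ISI) == 2

    def test_every_beat(self):
        ev = events_with_itis([0.42] * 10)
        assert detect_tap_interval(ev, ISI) == 1

    def test_tie_breaks_to_smaller_multiple(self):
        ev = events_with_itis([1.5 * ISI] * 10)  # midpoint of 1x and 2x
        assert detect_tap_interval(ev, ISI) == 1

    def test_too_few_taps(self):
        with pytest.raises(ValueError):
            detect_tap_interval(TapEventSeries(np.array([1.0, 2.0])), ISI)

    @pytest.mark.parametrize("m,excluded", [(1, True), (2, False), (3, True)])
    def test_wrong_rate_exclusion(self, m, excluded):
        assert exclude_wrong_rate(m) is excluded


class TestPhaseDetection:
    def test_exact_odd(self):
        stim = generate_stimulus_train(2.4, 39.5)
        ev = TapEventSeries(stim.onsets[2::2])  # 1-based odd beats 3,5,...
        assert detect_phase(ev, stim) == "odd"

    def test_exact_even(self):
        stim = generate_stimulus_train(2.4, 39.5)
        ev = TapEventSeries(stim.onsets[3::2])  # 1-based even beats 4,6,...
        assert detect_phase(ev, stim) == "even"

    def test_jittered_recovery(self, rng):
        stim = generate_stimulus_train(2.4, 39.5)
        hits = 0
        for _ in range(20):
            taps = stim.onsets[2::2] + rng.normal(0, 0.030, len(stim.onsets[2::2]))
            hits += detect_phase(TapEventSeries(np.sort(taps)), stim) == "odd"
        assert hits == 20


class TestCleaning:
    def test_trim_initial(self):
        ev = TapEventSeries(np.arange(12, dtype=float))
        out = trim_initial_taps(ev, 5)
        assert len(out) == 7
        assert all(r == "initial_trim" for _, r in out.discarded)
        assert len(trim_initial_taps(TapEventSeries(np.arange(5.0)), 5)) == 0
        empty = TapEventSeries(np.array([]))
        assert len(trim_initial_taps(empty, 5)) == 0

    def test_equal_intervals_no_pause_removal(self):
        ev = events_with_itis([0.83] * 12)
        assert remove_pause_taps(ev) is ev

    def test_single_pause_removed(self):
        itis = [0.83] * 9 + [3.5]
        ev = events_with_itis(itis)
        # independent check of the stated convention
        q1, q3 = np.percentile(itis, [25, 75])
        assert 3.5 > q3 + 3 * (q3 - q1)
        out = remove_pause_taps(ev)
        assert len(out) == len(ev) - 1
        assert out.discarded[0][0] == pytest.approx(ev.tap_times[-1])
        assert out.discarded[0][1] == "pause_outlier"

    def test_two_pauses_single_pass(self):
        itis = [0.83] * 5 + [3.5] + [0.83] * 5 + [4.0] + [0.83] * 3
        out = remove_pause_taps(events_with_itis(itis))
        assert len(out.discarded) == 2

    def test_too_few_taps_noop(self):
        ev = TapEventSeries(np.array([1.0, 2.0, 9.0]))
        assert remove_pause_taps(ev) is ev


class TestAngles:
    def setup_method(self):
        self.stim = generate_stimulus_train(2.4, 39.5)
        self.period = 2 * self.stim.isi

    def angle_of(self, offset):
        anchor = self.stim.onsets[4]  # a 1-based odd stimulus
        ev = TapEventSeries(np.array([anchor + offset]))
        return taps_to_angles(ev, self.stim, "odd")[0]

    def test_on_anchor(self):
        assert self.angle_of(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_period(self):
        assert self.angle_of(self.period / 4) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_half_period_maps_to_positive_pi(self):
        assert self.angle_of(self.period / 2) == pytest.approx(np.pi, abs=1e-9)

    def test_anticipation_is_negative(self):
        assert self.angle_of(-0.05) < 0


class TestMeanResultant:
    def test_degenerate(self):
        r, d = mean_resultant(np.zeros(10))
        assert (r, d) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_symmetric_cancellation(self):
        r, _ = mean_resultant(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_two_angles(self):
        r, d = mean_resultant(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(math.sqrt(2) / 2, abs=1e-9)
        assert d == pytest.approx(np.pi / 4, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_resultant(np.array([]))

    def test_brute_force_oracle_equivalence(self, rng):
        """R from the implementation vs an explicit sum of cos/sin terms."""
        for _ in range(1000):
            ang = rng.uniform(-np.pi, np.pi, rng.integers(1, 60))
            r, d = mean_resultant(ang)
            c, s = np.cos(ang).sum() / len(ang), np.sin(ang).sum() / len(ang)
            assert abs(r - math.hypot(c, s)) < 1e-12
            if r > 1e-9:
                assert abs(math.atan2(s, c) - d) < 1e-9


class TestLogit:
    def test_symmetry_point(self):
        assert logit_transform(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_logistic(self):
        assert logit_transform(0.7310586) == pytest.approx(1.0, abs=1e-5)

    def test_clamped_at_one(self):
        assert logit_transform(1.0, 1e-6) == pytest.approx(math.log((1 - 1e-6) / 1e-6), abs=1e-9)
        assert logit_transform(0.0, 1e-6) == pytest.approx(-logit_transform(1.0, 1e-6))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            logit_transform(1.2)


class TestRayleigh:
    def test_identical_angles(self):
        p = rayleigh_test(np.full(20, 0.7))
        assert p is not None and p < 1e-6

    def test_small_n_undefined(self):
        assert rayleigh_test(np.array([0.1, 0.2, 0.3])) is None

    def test_matches_pingouin(self, rng):
        """Cross-check the approximation against an independent implementation."""
        import pingouin as pg

        for _ in range(20):
            ang = rng.vonmises(0, rng.uniform(0, 2), 30)
            _, p_ref = pg.circ_rayleigh(ang)
            assert rayleigh_test(ang) == pytest.approx(p_ref, rel=1e-6, abs=1e-12)

    def test_null_rejection_rate(self, rng):
        rejections = sum(
            rayleigh_test(rng.vonmises(0, 0, 40)) < 0.05 for _ in range(1000)
        )
        assert 30 <= rejections <= 72  # binomial 99.9% band around 5%


class TestScoreTrial:
    def test_noise_free_end_to_end(self, noise_free_trial):
        sc = score_trial(noise_free_trial)
        assert not sc.excluded
        assert sc.vector_length == pytest.approx(1.0, abs=1e-12)
        assert sc.parity == "odd"
        assert sc.multiplier_detected == 2
        assert sc.rayleigh_p < 1e-6

    def test_every_beat_tapper_excluded(self):
        trial = simulate_tapper(
            CONDITIONS["A"], TapperParams(kappa=20.0, period_multiplier=1), 3
        )
        sc = score_trial(trial)
        assert sc.excluded and sc.exclusion_reason == "wrong_rate"
        assert sc.multiplier_detected == 1

    def test_even_locked_tapper(self, rng):
        trial = simulate_tapper(
            CONDITIONS["A"], TapperParams(kappa=4.0, start_beat=4, mean_phase=0.0), 11
        )
        sc = score_trial(trial)
        assert sc.parity == "even"
        assert abs(sc.vector_length - bessel_ratio(4.0)) < 0.1

    def test_too_few_taps_flagged(self):
        stim = generate_stimulus_train(2.4, 39.5)
        trial = TapTrial(
            participant_id="p",
            condition=CONDITIONS["A"],
            events=TapEventSeries(stim.onsets[2:20:2]),
            reference_stimuli=stim,
        )
        sc = score_trial(trial, ScoringConfig(min_taps=8))
        assert sc.excluded and sc.exclusion_reason == "too_few_taps"


class TestInvariances:
    def test_translation_invariance(self, rng):
        stim = generate_stimulus_train(2.4, 39.5)
        taps = np.sort(stim.onsets[2::2] + rng.normal(0, 0.05, 47))
        base = taps_to_angles(TapEventSeries(taps), stim, "odd")
        shift = 2.341
        stim_shifted = StimulusSequence(
            onsets=stim.onsets + shift, rate=stim.rate, duration=stim.duration + shift,
            modality=stim.modality,
        )
        shifted = taps_to_angles(TapEventSeries(taps + shift), stim_shifted, "odd")
        r0, d0 = mean_resultant(base)
        r1, d1 = mean_resultant(shifted)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_one_beat_period_shift_preserves_score(self, rng):
        stim = generate_stimulus_train(2.4, 39.5)
        period = 2 * stim.isi
        taps = np.sort(stim.onsets[2:80:2] + rng.normal(0, 0.05, 39))
        r0, d0 = mean_resultant(taps_to_angles(TapEventSeries(taps), stim, "odd"))
        r1, d1 = mean_resultant(taps_to_angles(TapEventSeries(taps + period), stim, "odd"))
        assert r1 == pytest.approx(r0, abs=1e-6)
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_scored_r_monotone_in_kappa(self, rng):
        means = []
        for kappa in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for _ in range(60):
                ang = rng.vonmises(0, kappa, 40)
                vals.append(mean_resultant(ang)[0])
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.floats(-math.pi, math.pi), min_size=1, max_size=50))
def test_vector_length_bounded(angles):
    r, d = mean_resultant(np.array(angles))
    assert 0.0 <= r <= 1.0
    assert -math.pi <= d <= math.pi
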