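"""Accuracy, SD and RMS precision, fixation selection, participant summary."""

import math

import numpy as np
import pytest

from gazeqc.geometry import ViewingGeometry
from gazeqc.ivt import FixationEvent
from gazeqc.metrics import (
    TrialQuality,
    precision_rms,
    precision_sd,
    select_longest_valid_fixation,
    summarize_participant,
    trial_accuracy,
)

DT = 1000.0 / 300.0


def make_event(x_px, y_px=None, t0=0.0):
    x = np.asarray(x_px, dtype=float)
    y = np.full_like(x, 540.0) if y_px is None else np.asarray(y_px, dtype=float)
    t = t0 + np.arange(len(x)) * DT
    return FixationEvent(start_ms=t[0], end_ms=t[-1], t_ms=t, x_px=x, y_px=y)


def angle_x(x, display, viewing):
    """Independent per-axis oracle: atan((x - cx) * pitch / d)."""
    pitch = display.pixel_pitch_cm[0]
    return math.degrees(
        math.atan((x - display.resolution_x / 2) * pitch / viewing.viewing_distance_cm)
    )


def angle_y(y, display, viewing):
    pitch = display.pixel_pitch_cm[1]
    return math.degrees(
        math.atan((y - display.resolution_y / 2) * pitch / viewing.viewing_distance_cm)
    )


def px_for_angle_x(a, display, viewing):
    pitch = display.pixel_pitch_cm[0]
    return display.resolution_x / 2 + viewing.viewing_distance_cm * math.tan(
        math.radians(a)
    ) / pitch


class TestSelectLongestValidFixation:
    def _ev(self, start, dur):
        n = max(2, int(round(dur / DT)) + 1)
        t = start + np.arange(n) * DT
        return FixationEvent(start, start + dur, t, np.full(n, 960.0), np.full(n, 540.0))

    def test_longest_wins(self):
        events = [self._ev(100, 100), self._ev(300, 400), self._ev(800, 200)]
        assert select_longest_valid_fixation(0.0, events) is events[1]

    def test_started_before_onset_is_ineligible(self):
        assert select_longest_valid_fixation(100.0, [self._ev(90, 500)]) is None

    def test_continuation_past_offset_is_eligible(self):
        # selection considers fixations in full even when they outlast the
        # trial window; only the start matters
        late = self._ev(1900, 800)
        assert select_longest_valid_fixation(0.0, [late]) is late

    def test_tie_goes_to_earlier_event(self):
        a, b = self._ev(100, 300), self._ev(600, 300)
        assert select_longest_valid_fixation(0.0, [b, a]) is a


class TestTrialAccuracy:
    def test_centroid_on_target_is_zero(self, display, viewing):
        ev = make_event([960.0, 960.0], [540.0, 540.0])
        assert trial_accuracy(ev, (960, 540), display, viewing) == 0.0

    def test_against_trig_oracle(self, display, viewing):
        ev = make_event([990.0, 990.0], [540.0, 540.0])
        oracle = abs(angle_x(990, display, viewing) - angle_x(960, display, viewing))
        assert trial_accuracy(ev, (960, 540), display, viewing) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_near_linear_at_small_angles(self, display, viewing):
        a1 = trial_accuracy(make_event([990.0] * 2), (960, 540), display, viewing)
        a2 = trial_accuracy(make_event([1020.0] * 2), (960, 540), display, viewing)
        assert a2 == pytest.approx(2 * a1, rel=0.01)


class TestPrecisionSd:
    def test_constant_trace(self, display, viewing):
        assert precision_sd(make_event([500.0] * 10), display, viewing) == pytest.approx(
            (0.0, 0.0), abs=1e-12
        )

    def test_three_point_formula(self, display, viewing):
        # x angular offsets of {-a, 0, +a} -> SD_x = a*sqrt(2/3), SD_y = 0
        a = 0.5
        xs = [px_for_angle_x(v, display, viewing) for v in (-a, 0.0, a)]
        sd = precision_sd(make_event(xs), display, viewing)
        assert sd[0] == pytest.approx(a * math.sqrt(2 / 3), abs=1e-12)
        assert sd[1] == 0.0

    def test_matches_two_pass_brute_force(self, display, viewing):
        rng = np.random.default_rng(7)
        x = rng.uniform(100, 1800, 37)
        y = rng.uniform(100, 1000, 37)
        got = precision_sd(make_event(x, y), display, viewing)
        ax = [angle_x(v, display, viewing) for v in x]
        mean = sum(ax) / len(ax)
        oracle = math.sqrt(sum((v - mean) ** 2 for v in ax) / len(ax))
        assert got[0] == pytest.approx(oracle, abs=1e-12)

    def test_requires_two_samples(self, display, viewing):
        assert precision_sd(make_event([500.0]), display, viewing) is None

    def test_time_reversal_invariance(self, display, viewing):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 1800, 20)
        y = rng.uniform(100, 1000, 20)
        fwd = precision_sd(make_event(x, y), display, viewing)
        rev = precision_sd(make_event(x[::-1], y[::-1]), display, viewing)
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestPrecisionRms:
    def test_constant_trace(self, display, viewing):
        assert precision_rms(make_event([500.0] * 10), display, viewing) == (0.0, 0.0)

    def test_alternating_one_degree(self, display, viewing):
        xs = [px_for_angle_x(v, display, viewing) for v in (0.0, 1.0, 0.0, 1.0)]
        rms = precision_rms(make_event(xs), display, viewing)
        assert rms[0] == pytest.approx(1.0, abs=1e-12)
        assert rms[1] == 0.0

    def test_matches_successive_difference_brute_force(self, display, viewing):
        rng = np.random.default_rng(9)
        y = rng.uniform(100, 1000, 23)
        got = precision_rms(make_event(np.full(23, 400.0), y), display, viewing)
        ay = [angle_y(v, display, viewing) for v in y]
        diffs = [(b - a) ** 2 for a, b in zip(ay, ay[1:])]
        assert got[1] == pytest.approx(math.sqrt(sum(diffs) / len(diffs)), abs=1e-12)

    def test_time_reversal_invariance(self, display, viewing):
        rng = np.random.default_rng(10)
        x = rng.uniform(100, 1800, 20)
        fwd = precision_rms(make_event(x), display, viewing)
        rev = precision_rms(make_event(x[::-1]), display, viewing)
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_white_noise_rms_to_sd_ratio_near_sqrt2(self, display, viewing):
        # i.i.d. noise: E[RMS] = sigma*sqrt(2) while SD -> sigma, so the
        # ratio concentrates near sqrt(2) for long fixations
        rng = np.random.default_rng(11)
        in_band = 0
        for _ in range(50):
            x = 960 + rng.normal(0, 10, 600)
            ev = make_event(x)
            sd = precision_sd(ev, display, viewing)[0]
            rms = precision_rms(ev, display, viewing)[0]
            in_band += 1.30 <= rms / sd <= 1.53
        assert in_band >= 47


class TestSummarizeParticipant:
    def _trial(self, acc, valid=True, outlier=False):
        return TrialQuality(
            target_id="center", valid=valid, outlier=outlier,
            accuracy_deg=acc if valid else None,
            sd_x_deg=0.1 if valid else None, sd_y_deg=0.1 if valid else None,
            rms_x_deg=0.1 if valid else None, rms_y_deg=0.1 if valid else None,
            n_valid_samples=100 if valid else 0,
        )

    def test_all_valid_unit_accuracies(self):
        p = summarize_participant("p", [self._trial(1.0)] * 5, 60.0)
        assert p.n_valid_trials == 5
        assert p.mean_accuracy_deg == 1.0

    def test_zero_valid_trials_discarded(self):
        p = summarize_participant("p", [self._trial(None, valid=False)] * 5, 60.0)
        assert p.discarded
        assert p.mean_accuracy_deg is None

    def test_mixed_validity_matches_brute_force(self):
        accs = [0.5, 2.0, None, 1.0, None]
        trials = [self._trial(a, valid=a is not None) for a in accs]
        trials[1].outlier = True  # excluded from means, still a valid trial
        p = summarize_participant("p", trials, 60.0)
        kept = [0.5, 1.0]
        assert p.n_valid_trials == 3
        assert p.mean_accuracy_deg == pytest.approx(sum(kept) / len(kept))

    def test_metrics_invariant_under_target_relabeling(self):
        trials = [self._trial(1.0 + i / 10) for i in range(5)]
        p1 = summarize_participant("p", trials, 60.0)
        relabeled = [
            TrialQuality(**{**t.__dict__, "target_id": f"t{i}"})
            for i, t in enumerate(trials)
        ]
        p2 = summarize_participant("p", relabeled, 60.0)
        assert p1.mean_accuracy_deg == p2.mean_accuracy_deg


class TestOracleEquivalence:
    def test_random_small_fixations_match_brute_force(self, display, viewing):
        # accuracy, SD and RMS on random 3-50 sample fixations against
        # independent loop-based implementations
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.uniform(1, 1919, n)
            y = rng.uniform(1, 1079, n)
            ev = make_event(x, y)
            tgt = (float(rng.uniform(0, 1920)), float(rng.uniform(0, 1080)))

            ax = [angle_x(v, display, viewing) for v in x]
            ay = [angle_y(v, display, viewing) for v in y]
            cx, cy = sum(x) / n, sum(y) / n
            acc_oracle = math.hypot(
                angle_x(cx, display, viewing) - angle_x(tgt[0], display, viewing),
                angle_y(cy, display, viewing) - angle_y(tgt[1], display, viewing),
            )
            mx, my = sum(ax) / n, sum(ay) / n
            sd_oracle = (
                math.sqrt(sum((v - mx) ** 2 for v in ax) / n),
                math.sqrt(sum((v - my) ** 2 for v in ay) / n),
            )
            rms_oracle = (
                math.sqrt(sum((b - a) ** 2 for a, b in zip(ax, ax[1:])) / (n - 1)),
                math.sqrt(sum((b - a) ** 2 for a, b in zip(ay, ay[1:])) / (n - 1)),
            )
            assert trial_accuracy(ev, tgt, display, viewing) == pytest.approx(
                acc_oracle, abs=1e-9
            )
            assert precision_sd(ev, display, viewing) == pytest.approx(
                sd_oracle, abs=1e-9
            )
            assert precision_rms(ev, display, viewing) == pytest.approx(
                rms_oracle, abs=1e-9
            )
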