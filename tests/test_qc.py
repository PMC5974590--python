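"""Outlier rule, inclusion decisions, run and group comparisons, report."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gazeqc.metrics import ParticipantQuality, TrialQuality
from gazeqc.pipeline import analyze_study, verify_recording, VerifyConfig
from gazeqc.qc import (
    OutlierRule,
    ReviewThresholds,
    compare_groups,
    compare_runs,
    flag_outlier_trials,
    inclusion_decision,
    render_report,
    summarize_group,
)
from gazeqc.simulate import simulate_cohort


def trial(acc, valid=True, outlier=False, target="center"):
    return TrialQuality(
        target_id=target, valid=valid, outlier=outlier,
        accuracy_deg=acc if valid else None,
        sd_x_deg=0.1 if valid else None, sd_y_deg=0.12 if valid else None,
        rms_x_deg=0.11 if valid else None, rms_y_deg=0.13 if valid else None,
        n_valid_samples=100 if valid else 0,
    )


def participant(pid, accs, run=""):
    trials = [trial(a, valid=a is not None) for a in accs]
    return ParticipantQuality(pid, trials, 60.0, run=run)


class TestFlagOutlierTrials:
    def test_all_equal_no_flags(self):
        assert not flag_outlier_trials([1.0] * 6).any()

    def test_single_wild_value_flagged(self):
        vals = [1.0, 1.1, 0.9, 1.0, 6.0]
        flags = flag_outlier_trials(vals)
        # brute-force oracle
        m = sum(vals) / len(vals)
        s = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
        oracle = [v > m + 1.5 * s for v in vals]
        assert list(flags) == oracle == [False] * 4 + [True]

    def test_upper_tail_only(self):
        # a value far *below* the mean is never flagged
        flags = flag_outlier_trials([5.0, 5.1, 4.9, 5.0, 0.1])
        assert not flags.any()

    def test_single_pass_contract(self):
        # applying the rule to the survivors could flag more; one pass only
        vals = [1.0, 1.0, 1.0, 1.0, 3.0, 20.0]
        first = flag_outlier_trials(vals)
        assert list(first) == [False] * 5 + [True]
        survivors = [v for v, f in zip(vals, first) if not f]
        # a second pass over the survivors would flag the 3.0 as well; the
        # tool deliberately stops after one pass
        assert flag_outlier_trials(survivors).sum() == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(1.0, 30)
        base = set(np.flatnonzero(flag_outlier_trials(vals)))
        perm = rng.permutation(30)
        permuted = np.flatnonzero(flag_outlier_trials(vals[perm]))
        assert {perm[i] for i in permuted} == base

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning):
            flags = flag_outlier_trials([1.0])
        assert not flags.any()

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            OutlierRule(k=0.0)


class TestInclusionDecision:
    def test_no_valid_trials_excluded(self):
        p = participant("p", [None] * 5)
        d = inclusion_decision(p)
        assert d.decision == "exclude"
        assert "no valid fixations" in d.reason

    def test_good_data_included(self):
        d = inclusion_decision(participant("p", [0.4, 0.5, 0.3, 0.6, 0.5]))
        assert d.decision == "include"

    def test_one_wild_trial_means_review_not_exclusion(self):
        # four accurate trials plus one 12-degree error: flag for human
        # review (the bad trial may just be a glance away), never auto-drop
        d = inclusion_decision(participant("p", [0.5, 0.6, 0.4, 0.5, 12.0]))
        assert d.decision == "review"

    def test_majority_outlier_trials_means_review(self):
        p = participant("p", [0.5, 0.6, 0.4])
        for t in p.trials:
            t.outlier = True
        assert inclusion_decision(p).decision == "review"

    def test_never_include_with_zero_valid(self):
        for n_trials in (0, 3, 5):
            p = participant("p", [None] * n_trials)
            assert inclusion_decision(p).decision == "exclude"


class TestCompareRuns:
    def test_identical_runs_show_no_difference(self):
        run1 = [participant(f"p{i}", [1.0 + i / 10] * 5, run="run1") for i in range(6)]
        run2 = [participant(f"p{i}", [1.0 + i / 10] * 5, run="run2") for i in range(6)]
        rep = compare_runs(run1, run2)
        assert rep["n_pairs"] == 6
        for m in rep["measures"].values():
            assert m["p_value"] == 1.0

    def test_six_pair_statistic_matches_exact_permutation_oracle(self):
        a = [1.00, 1.20, 0.90, 1.50, 1.10, 0.80]
        b = [1.13, 1.42, 1.21, 1.95, 1.04, 1.06]  # distinct |differences|
        run1 = [participant(f"p{i}", [v] * 5) for i, v in enumerate(a)]
        run2 = [participant(f"p{i}", [v] * 5) for i, v in enumerate(b)]
        rep = compare_runs(run1, run2)["measures"]["accuracy"]

        # exhaustive signed-rank null: enumerate all 2^6 sign assignments
        d = np.array(a) - np.array(b)
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        w = min(w_plus, ranks.sum() - w_plus)
        null = []
        for signs in itertools.product([0, 1], repeat=6):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            null.append(min(wp, ranks.sum() - wp))
        p_exact = sum(v <= w for v in null) / len(null)
        assert rep["statistic"] == pytest.approx(w)
        assert rep["p_value"] == pytest.approx(p_exact, abs=1e-12)

    def test_unmatched_participants_counted_not_paired(self):
        run1 = [participant("a", [1.0] * 5), participant("b", [1.0] * 5)]
        run2 = [participant("b", [1.1] * 5), participant("c", [1.2] * 5)]
        rep = compare_runs(run1, run2)
        assert rep["n_pairs"] == 1
        assert rep["n_unmatched_run1"] == 1
        assert rep["n_unmatched_run2"] == 1
        assert rep["low_power"]

    def test_discarded_participants_never_pair(self):
        run1 = [participant("a", [None] * 5), participant("b", [1.0] * 5)]
        run2 = [participant("a", [1.0] * 5), participant("b", [1.2] * 5)]
        assert compare_runs(run1, run2)["n_pairs"] == 1


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {
            "g1": [participant(f"a{i}", [1.0 + i / 10] * 5) for i in range(5)],
            "g2": [participant(f"b{i}", [1.0 + i / 10] * 5) for i in range(5)],
        }
        rep = compare_groups(g)
        pw = rep["measures"]["accuracy"]["pairwise"]["g1 vs g2"]
        assert pw["U"] == pytest.approx(12.5)  # null-symmetric n1*n2/2
        assert not pw["significant"]

    def test_tiny_separated_groups_match_exhaustive_rank_oracle(self):
        g = {
            "lo": [participant(f"a{i}", [v] * 5) for i, v in enumerate([1.0, 2.0, 3.0])],
            "hi": [participant(f"b{i}", [v] * 5) for i, v in enumerate([4.0, 5.0, 6.0])],
        }
        pw = compare_groups(g)["measures"]["accuracy"]["pairwise"]["hi vs lo"]
        # exhaustive: of C(6,3)=20 rank splits, only 1 is as extreme each way
        assert pw["U"] in (0.0, 9.0)
        assert pw["p_value"] == pytest.approx(2 / 20, abs=1e-12)
        assert not pw["significant"]  # 0.1 > 0.008

    def test_small_group_omitted_with_warning(self):
        g = {
            "ok": [participant(f"a{i}", [1.0] * 5) for i in range(3)],
            "tiny": [participant("z", [1.0] * 5)],
        }
        with pytest.warns(UserWarning, match="tiny"):
            rep = compare_groups(g)
        assert "tiny" not in rep["groups"]

    def test_shapiro_screen_reported_per_group(self):
        rng = np.random.default_rng(3)
        g = {
            lab: [participant(f"{lab}{i}", [float(v)] * 5)
                  for i, v in enumerate(rng.normal(1.0, 0.2, 8))]
            for lab in ("g1", "g2")
        }
        rep = compare_groups(g)
        sw = rep["measures"]["accuracy"]["shapiro"]
        assert set(sw) == {"g1", "g2"}
        assert all(0 <= v["p_value"] <= 1 for v in sw.values())

    def test_simulated_age_groups_power(self, verify_config):
        # four cohorts with increasingly poor presets: the omnibus test on
        # accuracy must reject at alpha=0.05 in nearly every replicate
        rejections = 0
        n_rep = 25
        for rep_i in range(n_rep):
            groups = {}
            for preset in ("adult", "school_age", "toddler_18m", "toddler_30m"):
                res = simulate_cohort(preset, 10, seed=9000 + rep_i)
                pqs = [verify_recording(r, verify_config) for r, _ in res["runs"]["run1"]]
                groups[preset] = pqs
            rep = compare_groups(groups)
            p = rep["measures"]["accuracy"]["kruskal"]["p_value"]
            rejections += p < 0.05
        assert rejections >= int(0.9 * n_rep)


class TestRenderReport:
    def test_empty_study(self):
        text = render_report([])
        assert "zero groups" in text

    def test_deterministic(self):
        ps = [participant(f"p{i}", [1.0, 1.2, 0.8, 1.1, 0.9]) for i in range(4)]
        s = summarize_group("adult", ps)
        assert render_report([s]) == render_report([s])

    def test_vendor_band_annotation(self):
        text = render_report([])
        assert "0.4-0.9" in text
        assert "0.04-0.15" in text
        assert "Vendor-claimed" in text

    def test_group_summary_consistency(self):
        # group means recomputed from the per-trial values equal the summary
        ps = [participant(f"p{i}", [1.0 + i / 7, 0.9, 1.3, 0.7, 1.1]) for i in range(5)]
        s = summarize_group("g", ps)
        accs = [t.accuracy_deg for p in ps for t in p.trials if t.valid]
        assert s.overall["accuracy_deg"] == pytest.approx(np.mean(accs), abs=1e-9)
        assert s.accuracy_range[0] <= np.mean([p.mean_accuracy_deg for p in ps])
        assert s.n_included + s.n_excluded == s.n_recruited


class TestAnalyzeStudy:
    def test_outlier_flags_and_decisions(self, verify_config):
        ps = [participant(f"p{i}", [1.0, 1.1, 0.9, 1.0, 1.05]) for i in range(4)]
        ps.append(participant("wild", [1.0, 1.0, 1.0, 1.0, 9.0]))
        result = analyze_study(ps, verify_config)
        assert result["n_outlier_trials"] == 1
        wild = next(p for p in ps if p.participant_id == "wild")
        assert [t.outlier for t in wild.trials] == [False] * 4 + [True]
        # with the outlier removed, wild's mean is fine -> included
        assert result["decisions"]["wild"].decision == "include"
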