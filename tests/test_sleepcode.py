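"""Epoch classification, bout segmentation, run assignment and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepconn import resp, sleepcode, synth

from conftest import deterministic_params, pure_timeline

TH = sleepcode.SleepThresholds()


def features(conc, cv, dom, valid=True):
    return sleepcode.EpochFeatures((0.0, 30.0), 60.0, cv, dom, conc, 1, valid=valid)


class TestExtractFeatures:
    def test_metronome_epoch_features(self, metronome_trace):
        breaths = resp.detect_breaths(metronome_trace)
        windows = sleepcode.epoch_windows(0.0, 120.0)
        feats = sleepcode.extract_features(metronome_trace, breaths, windows)
        assert len(feats) == 4
        for f in feats:
            assert f.valid
            assert f.mean_rate == pytest.approx(60.0, abs=0.5)
            assert f.rate_cv <= 0.01
            assert f.dominant_freq == pytest.approx(1.0)
            assert f.spectral_concentration >= 0.7
            assert sleepcode.classify_epoch(f) == "QS"

    def test_two_tone_trace_broad_spectrum(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 0.9 * t) + np.sin(2 * np.pi * 1.3 * t)
        trace = resp.RespirationTrace(x, fs)
        breaths = resp.detect_breaths(trace)
        feats = sleepcode.extract_features(trace, breaths,
                                           sleepcode.epoch_windows(0.0, 60.0))
        for f in feats:
            assert f.n_spectral_peaks >= 2
            assert f.spectral_concentration <= 0.6

    def test_flat_trace_invalid_features(self):
        fs = 500.0
        trace = resp.RespirationTrace(np.zeros(int(60 * fs)), fs)
        feats = sleepcode.extract_features(trace, None,
                                           sleepcode.epoch_windows(0.0, 60.0))
        assert all(not f.valid for f in feats)
        assert all(sleepcode.classify_epoch(f) == "IND" for f in feats)


class TestClassifyEpoch:
    @pytest.mark.parametrize("conc,cv,dom,expected", [
        (0.9, 0.02, 1.0, "QS"),     # narrow 1 Hz peak, metronomic
        (0.3, 0.25, 1.2, "AS"),     # diffuse spectrum, irregular rate
        (0.9, 0.02, 3.0, "IND"),    # outside the physiological band
        (0.58, 0.09, 1.0, "IND"),   # between the QS and AS bands
        (0.9, 0.25, 1.0, "AS"),     # concentrated but irregular
        (0.3, 0.02, 0.2, "IND"),    # below the band
    ])
    def test_rule_table(self, conc, cv, dom, expected):
        assert sleepcode.classify_epoch(features(conc, cv, dom), TH) == expected

    def test_invalid_features_never_raise(self):
        assert sleepcode.classify_epoch(
            sleepcode.EpochFeatures.invalid((0.0, 30.0)), TH) == "IND"


class TestSegmentStates:
    def test_short_intrusion_relabeled_ind(self):
        # a 30-s AS blip inside long quiet sleep becomes IND; the flanking
        # QS bouts (210 s each) satisfy the minimum duration and survive
        labels = ["QS"] * 7 + ["AS"] + ["QS"] * 7
        bouts = sleepcode.segment_states(labels, epoch_s=30.0)
        assert [b.label for b in bouts] == ["QS", "IND", "QS"]
        assert bouts[1].duration == 30.0
        assert bouts[0].duration == 210.0

    def test_fragments_below_minimum_all_demoted(self):
        # every AS/QS stretch here is under 3 minutes, so nothing is codable
        labels = ["QS"] * 5 + ["AS"] + ["QS"] * 5
        bouts = sleepcode.segment_states(labels, epoch_s=30.0)
        assert [b.label for b in bouts] == ["IND"]

    def test_uniform_sequence_single_bout(self):
        bouts = sleepcode.segment_states(["AS"] * 20, epoch_s=30.0)
        assert len(bouts) == 1
        assert bouts[0] == sleepcode.SleepBout("AS", 0.0, 600.0)

    def test_exactly_180s_bout_kept(self):
        labels = ["QS"] * 6 + ["AS"] * 6 + ["QS"] * 6
        bouts = sleepcode.segment_states(labels, epoch_s=30.0)
        assert [b.label for b in bouts] == ["QS", "AS", "QS"]

    @given(st.lists(st.sampled_from(["AS", "QS", "IND"]), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_invariants(self, labels):
        epoch_s = 30.0
        bouts = sleepcode.segment_states(labels, epoch_s=epoch_s)
        # tiling
        assert bouts[0].start == 0.0
        assert bouts[-1].end == pytest.approx(len(labels) * epoch_s)
        for a, b in zip(bouts, bouts[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.label != b.label
        # minimum state duration
        for b in bouts:
            if b.label in ("AS", "QS"):
                assert b.duration >= 180.0 - 1e-9
        # idempotence: re-coding the bout labels reproduces the bouts
        relabeled = []
        for b in bouts:
            relabeled += [b.label] * int(round(b.duration / epoch_s))
        assert sleepcode.segment_states(relabeled, epoch_s=epoch_s) == bouts
        # label-permutation equivariance
        swap = {"AS": "QS", "QS": "AS", "IND": "IND"}
        swapped = sleepcode.segment_states([swap[l] for l in labels], epoch_s=epoch_s)
        assert [(swap[b.label], b.start, b.end) for b in bouts] == \
               [(b.label, b.start, b.end) for b in swapped]


class TestAssignRunState:
    BOUTS = [sleepcode.SleepBout("AS", 0.0, 600.0),
             sleepcode.SleepBout("QS", 600.0, 1500.0),
             sleepcode.SleepBout("IND", 1500.0, 1800.0)]

    def run(self, onset):
        return synth.RunBoundary("run01", onset)

    def assign(self, onset, fd=0.03):
        (a,) = sleepcode.assign_run_state(self.BOUTS, [self.run(onset)],
                                          {"run01": fd})
        return a

    def test_fully_inside_qs_included(self):
        a = self.assign(700.0)
        assert (a.label, a.included, a.exclusion_reason) == ("QS", True, "none")

    def test_straddling_transition_is_ind(self):
        a = self.assign(500.0)  # crosses AS -> QS at 600 s
        assert a.label == "IND" and a.exclusion_reason == "indeterminate"

    def test_inside_ind_bout(self):
        a = self.assign(1550.0)
        assert a.label == "IND" and not a.included

    def test_motion_exclusion(self):
        a = self.assign(100.0, fd=0.2)
        assert (a.label, a.included, a.exclusion_reason) == ("AS", False, "motion")

    def test_fd_threshold_boundary_excludes(self):
        assert not self.assign(100.0, fd=0.15).included
        assert self.assign(100.0, fd=0.1499).included

    def test_outside_coded_interval_uncodable(self):
        a = self.assign(1700.0)  # run end 1880 > coded end 1800
        assert a.exclusion_reason == "uncodable"

    def test_run_touching_bout_end_is_covered(self):
        a = self.assign(420.0)  # run exactly [420, 600) inside AS
        assert a.label == "AS"

    def test_every_run_assigned_once(self):
        runs = [synth.RunBoundary(f"run{k}", 200.0 * k) for k in range(5)]
        fds = {r.run_id: 0.03 for r in runs}
        out = sleepcode.assign_run_state(self.BOUTS, runs, fds)
        assert [a.run_id for a in out] == [r.run_id for r in runs]
        for a in out:
            assert a.included == (a.label in ("AS", "QS") and a.mean_fd < 0.15)


class TestBookkeeping:
    def test_summary_from_assignments(self):
        mk = sleepcode.RunStateAssignment
        assignments = [
            mk("r1", "AS", 0.03, True, "none"),
            mk("r2", "AS", 0.20, False, "motion"),
            mk("r3", "QS", 0.03, True, "none"),
            mk("r4", "IND", 0.03, False, "indeterminate"),
        ]
        s = sleepcode.coding_summary(assignments, n_infants=2)
        assert (s.n_runs, s.n_coded, s.n_as, s.n_qs) == (4, 3, 2, 1)
        assert s.n_excluded_motion_as == 1 and s.n_excluded_motion_qs == 0
        assert s.n_analysed == 2
        assert s.pct_coded == pytest.approx(75.0)
        assert s.minutes_per_infant == pytest.approx(3.0)

    def test_empty_study_no_division_errors(self):
        s = sleepcode.coding_summary([], n_infants=0)
        assert s.pct_coded == 0.0 and s.minutes_per_infant == 0.0

    def test_chi_square_symmetric_counts(self):
        chi2, p = sleepcode.state_count_test(10, 10)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_hand_value(self):
        chi2, _ = sleepcode.state_count_test(30, 10)
        assert chi2 == pytest.approx(10.0)

    def test_chi_square_observed_study_counts(self):
        # standard equal-expectation statistic for a 36/13 split
        chi2, p = sleepcode.state_count_test(36, 13)
        assert chi2 == pytest.approx(10.80, abs=0.005)
        assert p < 0.01

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            sleepcode.state_count_test(0, 0)


class TestConcordance:
    def test_ind_epochs_excluded_from_denominator(self):
        pred = ["AS", "IND", "QS", "AS"]
        truth = ["AS", "QS", "QS", "QS"]
        assert sleepcode.concordance(pred, truth) == pytest.approx(2.0 / 3.0)

    def test_all_ind_is_nan(self):
        assert np.isnan(sleepcode.concordance(["IND"], ["AS"]))

    def test_single_session_end_to_end(self):
        from sleepconn.pipeline import session_concordance
        assert session_concordance(123) >= 0.8
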