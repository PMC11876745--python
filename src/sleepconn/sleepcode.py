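"""Active/quiet sleep coding from respiration, and per-run state assignment.

Infants cycle between two sleep states.  Active sleep (AS, the REM
analogue) shows fast, irregular breathing whose power spectrum is broad
with multiple peaks; quiet sleep (QS, the non-REM analogue) shows slow,
rhythmic breathing with a narrow spectral peak near 1 Hz.  Epochs meeting
neither profile are coded indeterminate (IND) and excluded from analysis.

The coder works on 30-s epochs:

1. per-epoch features from the band-passed trace and detected breaths
   (mean rate, rate variability, dominant frequency, spectral
   concentration, peak count),
2. a rule-based AS/QS/IND label per epoch,
3. merging into bouts with a 3-minute minimum AS/QS duration (one whole
   functional run), and
4. one state per functional run: a run is AS (QS) only if a single AS (QS)
   bout covers it entirely, and it enters analysis only if its mean
   framewise displacement is below 0.15 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .errors import InsufficientSignalError
from .resp import BreathSeries, RespirationTrace, instantaneous_rate_cv, welch_psd

__all__ = [
    "SleepThresholds",
    "EpochFeatures",
    "SleepBout",
    "RunStateAssignment",
    "CodingSummary",
    "epoch_windows",
    "extract_features",
    "classify_epoch",
    "segment_states",
    "assign_run_state",
    "coding_summary",
    "summary_from_counts",
    "state_count_test",
    "concordance",
]

AS, QS, IND = "AS", "QS", "IND"

#: Mean FD (mm) at or above which a run is excluded from analysis.
FD_EXCLUSION_MM = 0.15

#: Minimum duration (s) of an AS or QS bout — one whole functional run.
MIN_BOUT_S = 180.0


@dataclass(frozen=True)
class SleepThresholds:
    """Decision thresholds for the epoch classifier.

    QS requires a concentrated spectrum (``conc >= conc_qs``), low rate
    variability (``cv <= cv_qs``) and a dominant frequency in the QS band.
    AS requires an in-band dominant frequency together with either a diffuse
    spectrum (``conc <= conc_as``) or high rate variability
    (``cv >= cv_as``).  Feature values falling between the QS and AS bands
    yield IND rather than a forced call.
    """

    conc_qs: float = 0.60
    conc_as: float = 0.55
    cv_qs: float = 0.08
    cv_as: float = 0.10
    qs_freq_band: tuple[float, float] = (0.3, 1.3)
    as_freq_band: tuple[float, float] = (0.3, 2.0)
    #: band (Hz) within which the dominant peak and concentration are evaluated
    eval_band: tuple[float, float] = (0.15, 2.5)
    #: half-width (Hz) of the concentration window around the dominant peak
    conc_halfwidth: float = 0.15
    #: relative height for counting secondary spectral peaks
    peak_rel_height: float = 0.25


@dataclass(frozen=True)
class EpochFeatures:
    """Respiratory features of one classification epoch."""

    window: tuple[float, float]
    mean_rate: float  # bpm
    rate_cv: float
    dominant_freq: float  # Hz
    spectral_concentration: float
    n_spectral_peaks: int
    valid: bool = True

    @staticmethod
    def invalid(window: tuple[float, float]) -> "EpochFeatures":
        return EpochFeatures(window, float("nan"), float("nan"), float("nan"),
                             float("nan"), 0, valid=False)


@dataclass(frozen=True)
class SleepBout:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout must have positive duration")
        if self.label not in (AS, QS, IND):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def covers(self, t0: float, t1: float) -> bool:
        return self.start <= t0 and self.end >= t1


@dataclass(frozen=True)
class RunStateAssignment:
    run_id: str
    label: str
    mean_fd: float
    included: bool
    exclusion_reason: str  # none | indeterminate | motion | uncodable


def epoch_windows(start: float, end: float, epoch_s: float = 30.0) -> list[tuple[float, float]]:
    """Contiguous non-overlapping epochs of `epoch_s` covering [start, end).

    A trailing partial epoch is dropped.
    """
    n = int(np.floor((end - start) / epoch_s + 1e-9))
    return [(start + i * epoch_s, start + (i + 1) * epoch_s) for i in range(n)]


def extract_features(trace: RespirationTrace, breaths: BreathSeries | None,
                     windows: Sequence[tuple[float, float]],
                     thresholds: SleepThresholds | None = None,
                     welch_window_s: float = 10.0,
                     overlap: float = 0.5) -> list[EpochFeatures]:
    """Per-epoch respiratory features from a band-passed trace.

    `breaths` is the breath series detected on the whole trace (pass None
    if detection failed; every epoch is then flagged invalid).  Epochs with
    too few breaths or an empty evaluation band also come back invalid and
    are coded IND downstream — never an exception.
    """
    th = thresholds or SleepThresholds()
    feats: list[EpochFeatures] = []
    for (t0, t1) in windows:
        if breaths is None:
            feats.append(EpochFeatures.invalid((t0, t1)))
            continue
        cv = instantaneous_rate_cv(breaths, (t0, t1))
        inside = (breaths.breath_times >= t0) & (breaths.breath_times < t1)
        if not np.isfinite(cv):
            feats.append(EpochFeatures.invalid((t0, t1)))
            continue
        idx = np.flatnonzero(inside)
        mean_ibi = float(np.mean(breaths.ibi[idx[0]: idx[-1]]))
        mean_rate = 60.0 / mean_ibi
        seg = trace.segment(t0, t1)
        try:
            psd = welch_psd(seg, trace.sampling_rate, welch_window_s, overlap)
        except ValueError:
            feats.append(EpochFeatures.invalid((t0, t1)))
            continue
        lo, hi = th.eval_band
        band = (psd.frequencies >= lo) & (psd.frequencies <= hi)
        if band.sum() < 3 or not np.any(psd.power[band] > 0):
            feats.append(EpochFeatures.invalid((t0, t1)))
            continue
        f_band = psd.frequencies[band]
        p_band = psd.power[band]
        dom = float(f_band[np.argmax(p_band)])
        near = np.abs(f_band - dom) <= th.conc_halfwidth
        conc = float(p_band[near].sum() / p_band.sum())
        peaks, _ = _signal.find_peaks(p_band, height=th.peak_rel_height * p_band.max())
        # argmax at the band edge is a peak find_peaks cannot see
        n_peaks = int(peaks.size) if np.argmax(p_band) in peaks else int(peaks.size) + 1
        feats.append(EpochFeatures((t0, t1), mean_rate, cv, dom, conc, n_peaks))
    return feats


def classify_epoch(features: EpochFeatures,
                   thresholds: SleepThresholds | None = None) -> str:
    """AS / QS / IND decision for one epoch.

    Invalid features always yield IND.
    """
    th = thresholds or SleepThresholds()
    if not features.valid or not np.isfinite(features.dominant_freq):
        return IND
    conc, cv, dom = (features.spectral_concentration, features.rate_cv,
                     features.dominant_freq)
    qs_lo, qs_hi = th.qs_freq_band
    as_lo, as_hi = th.as_freq_band
    if conc >= th.conc_qs and cv <= th.cv_qs and qs_lo <= dom <= qs_hi:
        return QS
    if as_lo <= dom <= as_hi and (conc <= th.conc_as or cv >= th.cv_as):
        return AS
    return IND


def segment_states(labels: Sequence[str], epoch_s: float = 30.0,
                   start: float = 0.0, min_bout_s: float = MIN_BOUT_S) -> list[SleepBout]:
    """Merge epoch labels into bouts and enforce the minimum state duration.

    Equal-label neighbours are merged; any AS or QS bout shorter than
    `min_bout_s` is relabeled IND (the minimum state duration equals one
    whole functional run); adjacent IND bouts are then merged.  The result
    tiles [start, start + n*epoch_s) exactly, and the operation is
    idempotent.
    """
    if not labels:
        return []
    bouts: list[SleepBout] = []
    run_start = start
    cur = labels[0]
    for i, lab in enumerate(list(labels[1:]) + [None]):  # type: ignore[list-item]
        if lab != cur:
            end = start + (i + 1) * epoch_s
            bouts.append(SleepBout(cur, run_start, end))
            run_start = end
            cur = lab
    demoted = [
        replace(b, label=IND)
        if b.label in (AS, QS) and b.duration < min_bout_s - 1e-9 else b
        for b in bouts
    ]
    merged: list[SleepBout] = []
    for b in demoted:
        if merged and merged[-1].label == b.label and abs(merged[-1].end - b.start) < 1e-9:
            merged[-1] = SleepBout(b.label, merged[-1].start, b.end)
        else:
            merged.append(b)
    assert all(b.duration >= min_bout_s - 1e-9 for b in merged if b.label in (AS, QS))
    return merged


def assign_run_state(bouts: Sequence[SleepBout], runs: Sequence["RunBoundary"],
                     mean_fd: dict[str, float],
                     fd_threshold: float = FD_EXCLUSION_MM) -> list[RunStateAssignment]:
    """One sleep-state assignment per functional run.

    A run is AS (QS) only when a single AS (QS) bout covers the whole run
    interval; runs straddling a transition or touching an IND bout are IND.
    Runs outside the coded interval are uncodable.  Inclusion additionally
    requires mean FD below `fd_threshold`.
    """
    out: list[RunStateAssignment] = []
    coded_start = bouts[0].start if bouts else 0.0
    coded_end = bouts[-1].end if bouts else 0.0
    for run in runs:
        t0, t1 = run.onset, run.onset + run.duration
        fd = float(mean_fd[run.run_id])
        if t0 < coded_start - 1e-9 or t1 > coded_end + 1e-9:
            out.append(RunStateAssignment(run.run_id, IND, fd, False, "uncodable"))
            continue
        label = IND
        for b in bouts:
            if b.covers(t0, t1):
                label = b.label
                break
        if label == IND:
            out.append(RunStateAssignment(run.run_id, IND, fd, False, "indeterminate"))
        elif fd >= fd_threshold:
            out.append(RunStateAssignment(run.run_id, label, fd, False, "motion"))
        else:
            out.append(RunStateAssignment(run.run_id, label, fd, True, "none"))
    return out


@dataclass(frozen=True)
class CodingSummary:
    """Run bookkeeping across a study; all percentages derived from counts."""

    n_runs: int
    n_coded: int
    n_as: int
    n_qs: int
    n_excluded_motion_as: int
    n_excluded_motion_qs: int
    n_analysed: int
    n_infants: int
    run_minutes: float
    pct_coded: float = field(init=False)
    total_minutes: float = field(init=False)
    as_minutes: float = field(init=False)
    qs_minutes: float = field(init=False)
    pct_qs_minutes: float = field(init=False)
    minutes_per_infant: float = field(init=False)

    def __post_init__(self) -> None:
        pct = 100.0 * self.n_coded / self.n_runs if self.n_runs else 0.0
        total = self.n_runs * self.run_minutes
        as_min = self.n_as * self.run_minutes
        qs_min = self.n_qs * self.run_minutes
        pct_qs = 100.0 * qs_min / total if total else 0.0
        per_inf = (self.n_analysed * self.run_minutes / self.n_infants
                   if self.n_infants else 0.0)
        for k, v in [("pct_coded", pct), ("total_minutes", total),
                     ("as_minutes", as_min), ("qs_minutes", qs_min),
                     ("pct_qs_minutes", pct_qs), ("minutes_per_infant", per_inf)]:
            object.__setattr__(self, k, v)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs, "n_coded": self.n_coded,
            "pct_coded": self.pct_coded, "n_as": self.n_as, "n_qs": self.n_qs,
            "n_excluded_motion_as": self.n_excluded_motion_as,
            "n_excluded_motion_qs": self.n_excluded_motion_qs,
            "n_analysed": self.n_analysed, "n_infants": self.n_infants,
            "total_minutes": self.total_minutes, "as_minutes": self.as_minutes,
            "qs_minutes": self.qs_minutes, "pct_qs_minutes": self.pct_qs_minutes,
            "minutes_per_infant": self.minutes_per_infant,
        }


def summary_from_counts(n_runs: int, n_as: int, n_qs: int,
                        n_excluded_motion_as: int = 0, n_excluded_motion_qs: int = 0,
                        n_infants: int = 1, run_minutes: float = 3.0) -> CodingSummary:
    """Summary directly from run counts (coded = AS + QS runs)."""
    n_coded = n_as + n_qs
    n_analysed = n_coded - n_excluded_motion_as - n_excluded_motion_qs
    return CodingSummary(n_runs, n_coded, n_as, n_qs, n_excluded_motion_as,
                         n_excluded_motion_qs, n_analysed, n_infants, run_minutes)


def coding_summary(assignments: Iterable[RunStateAssignment], n_infants: int,
                   run_minutes: float = 3.0) -> CodingSummary:
    """Summary computed from per-run assignments across all infants.

    A run counts as coded when its label is AS or QS (motion-excluded runs
    are coded, just not analysed).
    """
    assignments = list(assignments)
    n_as = sum(a.label == AS for a in assignments)
    n_qs = sum(a.label == QS for a in assignments)
    return CodingSummary(
        n_runs=len(assignments), n_coded=n_as + n_qs, n_as=n_as, n_qs=n_qs,
        n_excluded_motion_as=sum(a.label == AS and a.exclusion_reason == "motion"
                                 for a in assignments),
        n_excluded_motion_qs=sum(a.label == QS and a.exclusion_reason == "motion"
                                 for a in assignments),
        n_analysed=sum(a.included for a in assignments),
        n_infants=n_infants, run_minutes=run_minutes,
    )


def state_count_test(n_as: int, n_qs: int) -> tuple[float, float]:
    """One-sample goodness-of-fit chi-square of AS vs QS run counts.

    Tests the observed split against equal expected counts (1 df).
    """
    if n_as + n_qs <= 0:
        raise ValueError("need at least one coded run")
    chi2, p = _stats.chisquare([n_as, n_qs])
    return float(chi2), float(p)


def concordance(predicted: Sequence[str], truth: Sequence[str]) -> float:
    """Fraction of non-IND predicted epochs agreeing with ground truth.

    Returns NaN when every epoch is IND.
    """
    if len(predicted) != len(truth):
        raise ValueError("label sequences differ in length")
    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    scored = pred != IND
    if not scored.any():
        return float("nan")
    return float(np.mean(pred[scored] == tru[scored]))
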