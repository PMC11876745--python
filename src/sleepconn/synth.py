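"""Seeded synthetic infant scanning sessions.

The raw data this pipeline targets (pressure-pad respiration time-locked to
infant fMRI) cannot be shared, so this module generates sessions with the
statistical structure the analysis assumes and full ground truth:

* an alternating active/quiet sleep (AS/QS) timeline with realistic bout
  durations, sleep onset in AS;
* breath-by-breath respiration — quiet sleep slow and metronomic
  (dominant frequency near 1 Hz), active sleep faster with high
  inter-breath and amplitude variability;
* functional run boundaries (90 volumes at TR 2 s, i.e. 3-minute runs);
* random-walk rigid-body motion rescaled to a target mean framewise
  displacement; and
* multivariate-Gaussian node time series whose state-conditional
  correlation structure can carry an injected Fisher-z effect on a chosen
  edge subset.

Everything is deterministic given explicit integer seeds; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import connectome as _conn
from .errors import GenerationError
from .resp import RespirationTrace

__all__ = [
    "BoutParams",
    "RespGenParams",
    "EffectMap",
    "StateTimeline",
    "RunBoundary",
    "Session",
    "QS_RESP_DEFAULT",
    "AS_RESP_DEFAULT",
    "generate_timeline",
    "generate_respiration",
    "generate_runs",
    "generate_motion",
    "default_base_correlation",
    "generate_node_timeseries",
    "generate_session",
    "simulate_study_connectomes",
]

AS, QS, IND = "AS", "QS", "IND"


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutParams:
    """Mean and minimum sleep-bout durations (seconds) per state.

    The long-run AS time fraction of the alternating timeline equals
    ``mean_as_s / (mean_as_s + mean_qs_s)``.  Defaults give an AS-heavy
    session (two-thirds of sleep time in AS) in which whole 3-minute
    functional runs land in quiet sleep only a minority of the time — the
    imbalanced regime the analysis has to cope with.
    """

    mean_as_s: float = 900.0
    mean_qs_s: float = 450.0
    min_bout_s: float = 180.0

    def __post_init__(self) -> None:
        if self.min_bout_s < 60.0:
            raise ValueError("min_bout_s must be at least 60 s")
        for m in (self.mean_as_s, self.mean_qs_s):
            if m < 0:
                raise ValueError("mean bout durations must be non-negative")

    @staticmethod
    def from_as_fraction(p_as: float, cycle_s: float = 800.0,
                         min_bout_s: float = 180.0) -> "BoutParams":
        """Bout means for a target AS time fraction over a mean AS+QS cycle."""
        if not 0.0 <= p_as <= 1.0:
            raise ValueError("p_as must lie in [0, 1]")
        return BoutParams(p_as * cycle_s, (1.0 - p_as) * cycle_s, min_bout_s)


@dataclass(frozen=True)
class RespGenParams:
    """Per-state breathing parameters.

    mean_rate_bpm
        Mean breathing rate in breaths per minute (physiological range
        20-80 bpm).
    rate_cv
        Coefficient of variation of the inter-breath interval (lognormal).
    amplitude_cv
        Coefficient of variation of the per-breath amplitude (lognormal,
        mean 1).
    noise_sd
        Additive white-noise SD in units of the unit pulse amplitude.
    sampling_rate
        Output sampling frequency, Hz.
    """

    mean_rate_bpm: float
    rate_cv: float
    amplitude_cv: float
    noise_sd: float = 0.05
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        if not 20.0 <= self.mean_rate_bpm <= 80.0:
            raise ValueError("mean_rate_bpm must lie in the physiological 20-80 bpm range")
        if self.rate_cv < 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("variability parameters must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


#: quiet sleep: ~1 Hz, metronomic, stable amplitude
QS_RESP_DEFAULT = RespGenParams(mean_rate_bpm=60.0, rate_cv=0.03, amplitude_cv=0.05)
#: active sleep: faster, irregular rate and amplitude
AS_RESP_DEFAULT = RespGenParams(mean_rate_bpm=75.0, rate_cv=0.20, amplitude_cv=0.30)


@dataclass(frozen=True)
class EffectMap:
    """Sleep-state effect injected into the node-series generator.

    `delta_z` (Fisher-z units) is added to the listed upper-triangle edges
    in active sleep relative to quiet sleep; `target_cohens_d` records the
    effect size the shift was calibrated against, if any.
    """

    edge_indices: tuple[int, ...]
    delta_z: float
    target_cohens_d: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_z):
            raise ValueError("delta_z must be finite")
        object.__setattr__(self, "edge_indices", tuple(int(i) for i in self.edge_indices))


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateTimeline:
    """Contiguous, ordered AS/QS bouts tiling [0, session_duration)."""

    entries: tuple[tuple[str, float, float], ...]
    session_duration: float

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("timeline must contain at least one bout")
        prev_end = 0.0
        for label, start, end in self.entries:
            if label not in (AS, QS):
                raise ValueError(f"unknown state label {label!r}")
            if end <= start:
                raise ValueError("bout duration must be positive")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("bouts must be contiguous and ordered")
            prev_end = end
        if abs(prev_end - self.session_duration) > 1e-9:
            raise ValueError("bouts must cover the full session")

    def state_at(self, t: float) -> str:
        for label, start, end in self.entries:
            if start <= t < end:
                return label
        return self.entries[-1][0]

    def state_fraction(self, label: str) -> float:
        tot = sum(e - s for lab, s, e in self.entries if lab == label)
        return tot / self.session_duration

    def run_truth(self, t0: float, t1: float) -> str:
        """True state of [t0, t1): the covering bout's label, else IND."""
        for label, start, end in self.entries:
            if start <= t0 + 1e-9 and end >= t1 - 1e-9:
                return label
        return IND

    def epoch_truth(self, windows: Sequence[tuple[float, float]]) -> list[str]:
        """Majority-occupancy state label per epoch window."""
        out = []
        for t0, t1 in windows:
            occ = {AS: 0.0, QS: 0.0}
            for label, start, end in self.entries:
                occ[label] += max(0.0, min(end, t1) - max(start, t0))
            out.append(AS if occ[AS] >= occ[QS] else QS)
        return out


def generate_timeline(session_duration: float, bout_params: BoutParams | None = None,
                      seed: int = 0) -> StateTimeline:
    """Alternating AS/QS timeline with exponential bout lengths.

    Sleep onset is in active sleep (newborns enter sleep through AS).  Bout
    duration = min_bout + Exponential(mean - min_bout); the final partial
    bout is absorbed into its predecessor so the minimum-duration invariant
    holds exactly.  A zero mean for either state forces a single-state
    session.
    """
    if session_duration <= 0:
        raise ValueError("session_duration must be positive")
    bp = bout_params or BoutParams()
    if bp.mean_qs_s == 0.0 or bp.mean_as_s == 0.0:
        only = AS if bp.mean_qs_s == 0.0 else QS
        return StateTimeline(((only, 0.0, session_duration),), session_duration)
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, float, float]] = []
    t = 0.0
    label = AS
    while t < session_duration - 1e-9:
        mean = bp.mean_as_s if label == AS else bp.mean_qs_s
        extra = rng.exponential(mean - bp.min_bout_s) if mean > bp.min_bout_s else 0.0
        dur = bp.min_bout_s + extra
        end = min(t + dur, session_duration)
        if session_duration - end < bp.min_bout_s:
            end = session_duration
        entries.append((label, t, end))
        t = end
        label = QS if label == AS else AS
    return StateTimeline(tuple(entries), session_duration)


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_respiration(timeline: StateTimeline,
                         params: dict[str, RespGenParams] | None = None,
                         seed: int = 0,
                         pulse_width_fraction: float = 0.6) -> RespirationTrace:
    """Breath-by-breath respiration synthesis over a sleep timeline.

    Inter-breath intervals are lognormal with the current state's mean rate
    and rate CV (positive, right-skewed — irregular AS breathing shows
    occasional long pauses).  Each breath is rendered as a raised-cosine
    pulse of width ``pulse_width_fraction x interval`` with lognormal
    amplitude jitter, and white noise is superposed.  With all CVs and
    noise at zero the trace is strictly periodic.
    """
    params = params or {AS: AS_RESP_DEFAULT, QS: QS_RESP_DEFAULT}
    fs = params[AS].sampling_rate
    if params[QS].sampling_rate != fs:
        raise ValueError("AS and QS sampling rates must agree")
    rng = np.random.default_rng(seed)
    n_samples = int(round(timeline.session_duration * fs))
    x = np.zeros(n_samples)

    t = 0.0
    while t < timeline.session_duration:
        p = params[timeline.state_at(t)]
        mean_ibi = 60.0 / p.mean_rate_bpm
        if p.rate_cv > 0:
            mu, sg = _lognormal_params(mean_ibi, p.rate_cv)
            ibi = float(rng.lognormal(mu, sg))
        else:
            ibi = mean_ibi
        if p.amplitude_cv > 0:
            mu, sg = _lognormal_params(1.0, p.amplitude_cv)
            amp = float(rng.lognormal(mu, sg))
        else:
            amp = 1.0
        width = pulse_width_fraction * ibi
        i0 = int(np.ceil(t * fs))
        i1 = min(n_samples, int(np.floor((t + width) * fs)) + 1)
        if i1 > i0:
            tau = np.arange(i0, i1) / fs - t
            x[i0:i1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / width))
        t += ibi

    # state-dependent additive white noise
    times = np.arange(n_samples) / fs
    for label in (AS, QS):
        sd = params[label].noise_sd
        if sd > 0:
            mask = np.array([timeline.state_at(tt) == label for tt in times[:: int(fs)]])
            # expand the per-second mask to samples (states change on >=60 s scales)
            full = np.repeat(mask, int(fs))[:n_samples]
            x[full] += rng.normal(0.0, sd, int(full.sum()))
    return RespirationTrace(x, fs, 0.0)


# ---------------------------------------------------------------------------
# runs & motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunBoundary:
    """Onset and length of one functional run on the session clock."""

    run_id: str
    onset: float
    n_volumes: int = 90
    tr: float = 2.0

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def end(self) -> float:
        return self.onset + self.duration


def generate_runs(timeline: StateTimeline, n_runs: int, tr: float = 2.0,
                  n_volumes: int = 90, start_offset: float = 0.0,
                  seed: int = 0) -> list[RunBoundary]:
    """Place non-overlapping ordered runs inside the session.

    Gaps (including before the first run) are a Dirichlet split of the free
    time after `start_offset`; raises GenerationError when the runs cannot
    be packed.
    """
    if n_runs == 0:
        return []
    run_len = n_volumes * tr
    free = timeline.session_duration - start_offset - n_runs * run_len
    if free < 0:
        raise GenerationError(
            f"{n_runs} runs of {run_len:.0f} s do not fit in a "
            f"{timeline.session_duration:.0f} s session (offset {start_offset:.0f} s)"
        )
    rng = np.random.default_rng(seed)
    gaps = rng.dirichlet(np.ones(n_runs + 1)) * free
    runs = []
    t = start_offset
    for k in range(n_runs):
        t += gaps[k]
        runs.append(RunBoundary(f"run{k + 1:02d}", t, n_volumes, tr))
        t += run_len
    return runs


def generate_motion(n_volumes: int, target_mean_fd: float, seed: int = 0,
                    head_radius: float = _conn.HEAD_RADIUS_MM) -> np.ndarray:
    """Random-walk 6-parameter motion rescaled to an exact target mean FD.

    Per-frame increments are white Gaussian (rotations pre-scaled by
    1/head_radius so they contribute comparably to FD); because FD is
    homogeneous of degree 1 in the parameters, a single rescaling sets the
    mean FD to `target_mean_fd` exactly.  A zero target yields an all-zero
    (static head) trace.
    """
    if target_mean_fd < 0:
        raise ValueError("target_mean_fd must be non-negative")
    if n_volumes < 2:
        raise ValueError("need at least two volumes")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    steps[:, 3:] /= head_radius
    motion = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    if target_mean_fd == 0.0:
        return np.zeros((n_volumes, 6))
    _, mean_fd = _conn.compute_fd(motion, head_radius)
    return motion * (target_mean_fd / mean_fd)


# ---------------------------------------------------------------------------
# node time series with injected edge effects
# ---------------------------------------------------------------------------

def default_base_correlation(n_nodes: int, rho: float = 0.35) -> np.ndarray:
    """Exponentially decaying base correlation ``r_ij = rho^|i-j|``.

    Positive definite for |rho| < 1, with moderate neighbour correlations —
    a minimal stand-in for the smooth community structure of parcellated
    fMRI (synthetic; carries no anatomical meaning).
    """
    idx = np.arange(n_nodes)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _state_correlations(n_nodes: int, base: np.ndarray | None,
                        effect: EffectMap | None) -> tuple[np.ndarray, np.ndarray]:
    base_r = default_base_correlation(n_nodes) if base is None else np.asarray(base, float)
    if base_r.shape != (n_nodes, n_nodes):
        raise ValueError("base correlation shape does not match n_nodes")
    r_qs = base_r.copy()
    r_as = base_r.copy()
    if effect is not None and effect.delta_z != 0.0 and effect.edge_indices:
        i_all, j_all = _conn.edge_pairs(n_nodes)
        m = _conn.n_edges(n_nodes)
        for e in effect.edge_indices:
            if not 0 <= e < m:
                raise ValueError(f"edge index {e} out of range for {n_nodes} nodes")
            i, j = int(i_all[e]), int(j_all[e])
            r_new = np.tanh(np.arctanh(r_as[i, j]) + effect.delta_z)
            r_as[i, j] = r_as[j, i] = r_new
    for name, r in ((QS, r_qs), (AS, r_as)):
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            edges = tuple(effect.edge_indices) if effect else ()
            raise GenerationError(
                f"{name} target correlation not positive definite after effect "
                f"injection on edges {edges}"
            ) from None
    return r_as, r_qs


def generate_node_timeseries(run_states: Sequence[str], n_nodes: int = 89,
                             base_correlation: np.ndarray | None = None,
                             effect: EffectMap | None = None,
                             n_volumes: int = 90, tr: float = 2.0,
                             seed: int = 0) -> tuple[list[_conn.NodeTimeSeries],
                                                     _conn.Connectome, _conn.Connectome]:
    """Per-run multivariate-Gaussian node series with a state-dependent effect.

    Returns one NodeTimeSeries per entry of `run_states` plus the exact
    state-conditional target connectomes (Fisher z of the generating
    correlations, diagonal 0) for AS and QS.
    """
    r_as, r_qs = _state_correlations(n_nodes, base_correlation, effect)
    chol = {AS: np.linalg.cholesky(r_as), QS: np.linalg.cholesky(r_qs)}
    rng = np.random.default_rng(seed)
    runs = []
    for k, state in enumerate(run_states):
        if state not in (AS, QS):
            raise ValueError(f"run state must be AS or QS, got {state!r}")
        data = rng.standard_normal((n_volumes, n_nodes)) @ chol[state].T
        runs.append(_conn.NodeTimeSeries(f"run{k + 1:02d}", data, tr))

    def to_z(r: np.ndarray) -> _conn.Connectome:
        z = np.arctanh(np.clip(r, -(1 - _conn.FISHER_Z_CLIP), 1 - _conn.FISHER_Z_CLIP))
        np.fill_diagonal(z, 0.0)
        return _conn.Connectome((z + z.T) / 2.0)

    return runs, to_z(r_as), to_z(r_qs)


# ---------------------------------------------------------------------------
# whole sessions and study-scale shortcuts
# ---------------------------------------------------------------------------

#: printed state-specific mean-FD magnitudes the motion generator emulates
STATE_MEAN_FD = {AS: 0.049, QS: 0.029, IND: 0.040}


@dataclass(frozen=True)
class Session:
    """One synthetic infant session with full ground truth."""

    infant_id: str
    timeline: StateTimeline
    respiration: RespirationTrace
    runs: tuple[RunBoundary, ...]
    true_run_states: tuple[str, ...]
    motion: dict[str, np.ndarray]
    tissue_means: dict[str, np.ndarray]
    node_series: dict[str, _conn.NodeTimeSeries]
    target_z_as: _conn.Connectome
    target_z_qs: _conn.Connectome
    pma_weeks: float = 45.9
    sex: int = 0
    seed: int = 0


def generate_session(session_s: float = 3600.0, n_runs: int = 5,
                     n_nodes: int = 89, n_volumes: int = 90, tr: float = 2.0,
                     bout_params: BoutParams | None = None,
                     resp_params: dict[str, RespGenParams] | None = None,
                     effect: EffectMap | None = None,
                     motion_outlier_prob: float = 0.08,
                     infant_id: str = "sub-01",
                     pma_weeks: float = 45.9, sex: int = 0,
                     seed: int = 0) -> Session:
    """Generate a complete session: timeline, respiration, runs, motion,
    tissue means and node time series.

    Per-run target mean FD is drawn around the state-specific magnitudes in
    STATE_MEAN_FD with lognormal jitter; with probability
    `motion_outlier_prob` a run is a motion outlier (target inflated 3-6x),
    producing occasional exclusions under the 0.15 mm rule.
    """
    ss = np.random.SeedSequence(seed)
    s_tl, s_resp, s_runs, s_motion, s_nodes, s_tissue = (
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(6))
    timeline = generate_timeline(session_s, bout_params, seed=s_tl)
    respiration = generate_respiration(timeline, resp_params, seed=s_resp)
    runs = generate_runs(timeline, n_runs, tr, n_volumes, seed=s_runs)
    truth = tuple(timeline.run_truth(r.onset, r.end) for r in runs)

    rng_m = np.random.default_rng(s_motion)
    motion, tissue = {}, {}
    for r, st in zip(runs, truth):
        target = STATE_MEAN_FD[st] * float(np.exp(0.20 * rng_m.standard_normal()))
        if rng_m.random() < motion_outlier_prob:
            target *= rng_m.uniform(3.0, 6.0)
        motion[r.run_id] = generate_motion(n_volumes, target,
                                           seed=int(rng_m.integers(2 ** 31)))
    rng_t = np.random.default_rng(s_tissue)
    for r in runs:
        raw = rng_t.standard_normal((n_volumes, 3))
        tissue[r.run_id] = gaussian_filter1d(raw, sigma=3.0, axis=0, mode="reflect")

    # node series only for runs whose truth is a single state; straddling
    # runs get QS-structure data (they are excluded downstream anyway)
    gen_states = [st if st in (AS, QS) else QS for st in truth]
    series, z_as, z_qs = generate_node_timeseries(
        gen_states, n_nodes, effect=effect, n_volumes=n_volumes, tr=tr, seed=s_nodes)
    node_series = {r.run_id: _conn.NodeTimeSeries(r.run_id, s.data, tr)
                   for r, s in zip(runs, series)}
    return Session(infant_id, timeline, respiration, tuple(runs), truth,
                   motion, tissue, node_series, z_as, z_qs,
                   pma_weeks=pma_weeks, sex=sex, seed=seed)


def _jitter_correlation(base_r: np.ndarray, sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Participant-level correlation: Fisher-z jitter on every edge.

    Individual connectomes differ; adding N(0, sd) in z units per edge
    realizes the participant random intercept the edgewise model assumes.
    The jitter is halved (up to 6 times) if it breaks positive
    definiteness.
    """
    if sd <= 0:
        return base_r
    n = base_r.shape[0]
    i, j = _conn.edge_pairs(n)
    noise = rng.normal(0.0, 1.0, i.size)
    scale = sd
    for _ in range(6):
        z = np.arctanh(np.clip(base_r[i, j], -0.999999, 0.999999)) + scale * noise
        r = np.eye(n)
        r[i, j] = r[j, i] = np.tanh(z)
        try:
            np.linalg.cholesky(r)
            return r
        except np.linalg.LinAlgError:
            scale /= 2.0
    raise GenerationError("could not generate a positive-definite participant "
                          "correlation matrix")


def simulate_study_connectomes(n_infants: int = 11, n_runs: int = 42,
                               n_qs_runs: int = 11, n_qs_infants: int = 4,
                               n_nodes: int = 89, n_volumes: int = 90,
                               effect: EffectMap | None = None,
                               participant_z_sd: float = 0.05,
                               seed: int = 0):
    """Study-scale edge data without the physiological layer.

    Distributes `n_runs` over `n_infants` as evenly as possible, assigns
    `n_qs_runs` quiet-sleep runs concentrated in the first `n_qs_infants`
    infants (the rest are active sleep), generates node series per run from
    a participant-specific correlation matrix (`participant_z_sd` of
    Fisher-z jitter realizes the participant random intercept), and returns
    ``(Z, design)`` where Z is (n_runs, n_edges) of Fisher-z edge values
    and design is a pandas DataFrame with participant, state, and plausible
    pma/sex/mean-FD covariates.
    """
    import pandas as pd

    if n_qs_runs > n_runs or n_qs_infants > n_infants:
        raise ValueError("infeasible study layout")
    per = np.full(n_infants, n_runs // n_infants)
    per[: n_runs % n_infants] += 1
    qs_quota = np.zeros(n_infants, dtype=int)
    remaining = n_qs_runs
    k = 0
    while remaining > 0:
        i = k % max(n_qs_infants, 1)
        if qs_quota[i] < per[i]:
            qs_quota[i] += 1
            remaining -= 1
        k += 1
        if k > 10 * n_qs_runs + 10:
            raise ValueError("cannot place the requested QS runs")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_infants + 1)
    rng_cov = np.random.default_rng(int(child[-1].generate_state(1)[0] % (2 ** 31)))
    rows, z_rows = [], []
    base_r = default_base_correlation(n_nodes)
    for i in range(n_infants):
        states = [QS] * qs_quota[i] + [AS] * (per[i] - qs_quota[i])
        s_i = int(child[i].generate_state(1)[0] % (2 ** 31))
        rng_i = np.random.default_rng(s_i)
        r_i = _jitter_correlation(base_r, participant_z_sd, rng_i)
        series, _, _ = generate_node_timeseries(
            states, n_nodes, base_correlation=r_i, effect=effect,
            n_volumes=n_volumes, seed=int(rng_i.integers(2 ** 31)))
        pma = float(np.clip(45.9 + 1.2 * rng_cov.standard_normal(), 42.0, 47.0))
        sex = int(rng_cov.integers(2))
        for st, ts in zip(states, series):
            z_rows.append(_conn.build_connectome(ts).edge_vector())
            fd = STATE_MEAN_FD[st] * float(np.exp(0.2 * rng_cov.standard_normal()))
            rows.append({"participant": f"sub-{i + 1:02d}",
                         "state": 1 if st == AS else 0,
                         "pma_weeks": pma, "sex": sex, "mean_fd": fd})
    design = pd.DataFrame(rows)
    return np.vstack(z_rows), design
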