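# Methods

`sleepconn` implements a desk-scale version of a feasibility analysis for
infant fMRI: code active sleep (AS) versus quiet sleep (QS) from
respiration recorded during scanning, assign one sleep state to each
time-locked functional run, build Fisher-z functional connectomes from
parcellated node time series, and compare the two states edge by edge with
linear mixed-effects models under Benjamini–Yekutieli (BY) false-discovery
control. Because raw infant physiological and imaging data of this kind
cannot generally be shared, a first-class synthetic-data module generates
sessions with the statistical structure the analysis assumes, including
full ground truth, so every stage is testable.

## Sleep-state coding from respiration

**Physiological model.** Infants breathe at roughly 20–80 breaths per
minute (bpm), i.e. respiratory fundamentals of 0.3–1.3 Hz. Quiet sleep
shows slow, metronomic breathing — a narrow respiratory power spectrum
with a single peak near 1 Hz — while active sleep shows faster breathing
with high inter-breath and amplitude variability, giving a broad,
multi-peaked spectrum.

**Signal conditioning.** The pressure-pad trace (500 Hz) is band-pass
filtered to 0.05–5 Hz with a 4th-order Butterworth high-pass cascaded with
a 4th-order Butterworth low-pass, applied forward–backward
(`sosfiltfilt`) so breath-peak times are not shifted. Butterworth is the
flattest-passband default among IIR designs; the orders are exposed in
`resp.bandpass`.

**Breath detection.** Local-maximum picking on the filtered trace with
(a) a 0.45 s refractory period (just above the 80 bpm ceiling) and (b) a
prominence threshold of 0.5 × the rolling 30-s standard deviation, which
adapts to slow amplitude drift. Traces with fewer than three detected
breaths raise `InsufficientSignalError` and are excluded from coding —
mirroring how noisy in-scanner physiological recordings are handled in
practice. No cardiac or scanner-artifact rejection is attempted.

**Epoch features.** Classification uses 30-s non-overlapping epochs (the
polysomnography convention; the spectral window below is what the staging
literature fixes, not the epoch). Per epoch:

- mean breathing rate `60 / mean(IBI)` and the coefficient of variation of
  the inter-breath intervals (sample, n−1 convention);
- a Welch power spectral density (Hann tapers, 10-s windows, 50 % overlap,
  mean averaging; 0.1 Hz resolution), evaluated in a 0.15–2.5 Hz band;
- the dominant frequency (band argmax), the spectral concentration
  (power within ±0.15 Hz of the dominant peak over band power), and the
  number of spectral peaks at ≥ 25 % of the maximum.

**Decision rule.** QS requires concentration ≥ 0.60, rate CV ≤ 0.08 and a
dominant frequency in 0.3–1.3 Hz; AS requires a dominant frequency in
0.3–2.0 Hz together with concentration ≤ 0.55 *or* rate CV ≥ 0.10;
anything else — including every epoch with invalid features — is
indeterminate (IND). Feature values falling between the QS and AS bands
deliberately yield IND rather than a forced call: the third category
exists precisely for ambiguous segments, which are excluded downstream.
The AS thresholds were calibrated once against the synthetic generator
(peak picking with a refractory period attenuates the detected rate CV of
fast irregular breathing to ≈ 0.13–0.14, and AS concentration sits near
0.5, so the commonly suggested 0.15 / 0.40 cut-offs leave most true-AS
epochs indeterminate). All thresholds are configuration fields.

**Bouts and runs.** Equal-label epochs merge into bouts; any contiguous
AS/QS stretch shorter than 3 minutes — exactly one functional run — is
demoted to IND, so no AS/QS bout under 180 s ever appears (hard
assertion). A functional run (90 volumes × TR 2 s = 180 s) receives a
state only when a single AS or QS bout covers its whole interval; runs
straddling a transition, touching an IND bout, or lying outside the coded
interval are IND/uncodable. An IND epoch inside an otherwise uniform
stretch therefore breaks run coverage — the conservative reading. A run
enters analysis only if additionally its mean framewise displacement is
below 0.15 mm.

**Bookkeeping.** `coding_summary` / `state_count_test` recompute all
percentages from counts (runs coded, AS/QS counts, minutes per state,
analysed minutes per infant) and test the AS/QS split against equal
expected counts with a 1-df goodness-of-fit chi-square. Note that for a
36 / 13 split this standard statistic is 10.80; published analyses of
such splits sometimes report other values because the expected
proportions behind them are not always stated.

## Connectome construction

The package starts at parcellated node time series (default 89 nodes);
image-space steps (registration, motion correction of volumes, atlas
warping) are out of scope and the generator emits node series directly.

- **Framewise displacement**: sum of absolute backward differences of the
  three translations plus 50 mm × the same for the three rotations — the
  field-standard formula; the head radius is a parameter.
- **Confounds** (30 columns, fixed order): intercept, linear and quadratic
  drifts, mean CSF/WM/GM signals, and a 24-parameter motion model (6
  rigid-body parameters, their backward-difference temporal derivatives
  with the first frame set to 0, and the squares of both). Removed by OLS;
  all-zero columns are dropped and residual rank deficiency raises with
  the offending column names.
- **Temporal smoothing**: Gaussian kernel whose transfer function
  `exp(−2π²σ²f²)` is 0.5 at the 0.12 Hz cutoff → σ ≈ 1.56 s (0.78 TR),
  truncated at ±4σ, reflection at the edges. "Approximate cutoff" is read
  as the half-amplitude point; other conventions are a one-line change.
- **Connectome**: pairwise Pearson correlations, clipped to
  ±(1 − 10⁻⁷), Fisher z-transformed (`atanh`), diagonal 0. Edges are
  vectorized as the row-major upper triangle (i < j), n(n−1)/2 values;
  matrix ↔ vector round-trips exactly.

The stage order is fixed and tested: confound regression → temporal
smoothing → connectome; motion-excluded runs never reach connectome
construction.

## Edgewise statistics

Each edge's Fisher-z value across analysed runs is modeled as

    z_edge = β₀ + β₁·state + (γ·covariates) + u_participant + ε,

state coded AS = 1 / QS = 0, `u` a participant random intercept,
optional covariates postmenstrual age (weeks), sex, and per-run mean FD.

**Solver.** Restricted maximum likelihood, specialized to a single
grouping factor: with θ = σ²_participant / σ²_residual the marginal
covariance is `V(θ) = I + θ·ZZᵀ`, whose inverse and determinant are
closed-form per participant block. The profiled REML criterion is
evaluated for all edges simultaneously as batched linear algebra over a
log-spaced θ grid ({0} ∪ 10⁻⁶…10⁴), followed by a vectorized
golden-section refinement within the bracketing grid cell. This makes a
3 916-edge analysis take well under a second, which the simulation-based
tests rely on. The fit is cross-checked against `statsmodels` `MixedLM`
(REML) in the test suite.

**Degrees of freedom.** Between–within rule:
`df = n_runs − n_participants − n_fixed` (fixed effects counted without
the intercept). When the REML estimate hits the θ = 0 boundary, when
every participant contributes one run, or when the between–within rule
leaves no residual df, the fit degenerates exactly to OLS and ordinary
residual df (`n − p`) are reported, with an `ols_fallback` flag per edge.
In the one-run-per-participant limit the state t statistic equals the
pooled two-sample t exactly.

- **FDR**: Benjamini–Yekutieli step-up with penalty `c(m) = Σ 1/i`
  (valid under arbitrary dependence), via
  `statsmodels.stats.multitest.multipletests`; a brute-force step-up
  oracle and BH-domination are asserted in tests.
- **Effect sizes**: `D = 2t/√df` (the standard two-group conversion for
  mixed-model t statistics), binned as |D| < 0.2 / small [0.2, 0.5) /
  medium [0.5, 0.8) / large ≥ 0.8, plus direction-conditional mean |D|.
- **Power**: two-sided two-sample normal approximation
  `n/group = 2(z₁₋α/₂ + z_power)²/d²` at a Bonferroni-corrected α,
  total = 2·⌈n/group⌉; a noncentral-t variant (`method="t"`) is available
  (at d = 0.8, α = 0.05, power 0.8 they give totals of 50 and 52). All
  assumptions (effect size, family α, test count, power, method) are
  explicit parameters because published sample-size claims rarely state
  all of them.

## Synthetic data generator

What it emulates, and the defaults (all configurable):

- **Timeline**: alternating AS/QS bouts, sleep onset in AS (newborns
  enter sleep through active sleep). Bout length = 180 s +
  Exp(mean − 180 s); mean AS bout 900 s, mean QS 450 s, so two-thirds of
  sleep time is AS, roughly three-quarters of codable runs are AS, and a
  realistic minority of runs straddle transitions. The AS time fraction
  equals `mean_AS/(mean_AS+mean_QS)` in expectation, with a small upward
  bias in finite sessions from the AS onset. The final partial bout is
  absorbed into its predecessor so the minimum bout duration holds
  exactly.
- **Respiration** (500 Hz): breath-by-breath synthesis. Inter-breath
  intervals are lognormal (positive, right-skewed, matching the
  occasional long pauses of active sleep) with QS 60 bpm / CV 0.03 and AS
  75 bpm / CV 0.20; each breath is a raised-cosine pulse of width
  0.6 × interval with lognormal amplitude jitter (CV 0.05 QS / 0.30 AS);
  white noise SD 0.05 of the unit pulse amplitude. With all CVs and noise
  zero the trace is strictly periodic — the deterministic limit used by
  the unit tests. Amplitude units are arbitrary: pressure-pad recordings
  have no calibrated physical unit.
- **Runs**: 90 volumes at TR 2 s; gaps are a Dirichlet split of free
  session time.
- **Motion**: a 6-parameter Gaussian random walk rescaled — FD is
  homogeneous of degree 1 — so mean FD matches its target exactly.
  Targets are drawn around state means of 0.049 mm (AS) / 0.029 mm (QS)
  with lognormal jitter; a configurable outlier probability (default
  0.08) inflates a run 3–6×, producing occasional exclusions under the
  0.15 mm rule.
- **Node series**: per-run multivariate Gaussian draws. The base
  correlation is `0.35^|i−j|` (positive definite by construction; a
  minimal synthetic stand-in with no anatomical meaning). Study-scale
  generation adds per-participant Fisher-z jitter (SD 0.05) to every
  edge, realizing the participant random intercept the model assumes.
  An injected sleep-state effect shifts chosen edges by `delta_z` in z
  units in AS; the exact state-conditional target connectomes are
  returned, and a shift that breaks positive definiteness raises with the
  offending edges listed. `stats.calibrate_delta_z` inverts the
  `D = 2t/√df` chain (run-level z sampling SD ≈ `1/√(T−3)`) so an
  injected effect lands on a requested Cohen's D.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no volumetric image simulation, no cardiac or
scanner-gradient contamination of the respiration channel beyond white
noise, no awake periods (all time is assumed asleep), no spatial
structure in the parcellation, and state-conditional rather than
continuously drifting connectivity. The concordance numbers on synthetic
sessions certify the coding logic, not field performance on noisy
in-scanner recordings.

## Problem sizes used by the shipped checks

The simulation-based checks run at the scale the analysis design
dictates: 50 one-hour sessions for coder concordance; 100 studies of 11
infants / 42 runs / 89 nodes (3 916 edges) for the no-effect FDR
property; 20 studies of 40 infants × 4 runs at 10 nodes for effect-size
recovery. The end-to-end demo config is 11 infants with 3–7 runs each in
one-hour sessions and completes in a few minutes on one CPU.

## Numerical choices and degenerate inputs

- Correlations are clipped before `atanh`; duplicated nodes stay finite,
  constant nodes raise with the node named.
- Welch requires at least one full 10-s window; shorter epochs are
  invalid → IND.
- Rate-CV windows need ≥ 3 breaths; fewer give NaN → IND (never an
  exception inside the coder).
- `segment_states` is idempotent and AS↔QS-permutation equivariant
  (property-tested).
- Every generator takes an explicit integer seed; there is no global
  random state, and identical seeds give bit-identical outputs (the
  pipeline rerun test asserts byte-identical CSVs).

## Known limitations

- The classifier thresholds are calibrated to this generator's breathing
  model; real pressure-pad data would need re-calibration against
  polysomnography, and the 80 %+ concordance observed here should not be
  quoted for real recordings.
- The between–within df rule is one convention among several for mixed
  models; with very small samples the OLS fallback is common and the
  per-edge flag should be inspected.
- A chi-square on AS/QS run counts treats runs as independent, which
  within-infant clustering violates; the statistic is reported for
  bookkeeping, not inference.
- The normal-approximation power formula is slightly liberal at small n;
  use `method="t"` for planning.
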