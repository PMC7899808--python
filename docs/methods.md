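# Methods

## Protocol and adherence scoring

A session schedule tiles `[0, T)` with repeating inhale → exhale → pause
intervals from a fixed pattern (defaults 4-2-4 s, `T` = 360 s). Intervals
are half-open, so a timestamp on a boundary belongs to the later phase, and
a trailing partial cycle is truncated rather than dropped — the session
duration is what is fixed, not the cycle count.

Adherence is overlap-based: a detected event credits a protocol interval
only where their labels match, giving a continuous per-interval coverage in
[0, 1]. A phase counts as followed "for its entire period" when coverage
reaches `full_threshold` = 0.9; detector latency makes exact 1.0
unattainable in practice, and the threshold is deliberately generous of a
~0.4-s onset lag on a 4-s phase. Gaps between events are treated as no
detection (no credit), never interpolated.

## Engine dynamics

The game state advances in fixed steps (`dt` = 0.05 s). Per step, with the
protocol phase `φ` and instantaneous correctness `c` (detected label at the
step midpoint equals `φ`):

* `φ` = inhale and `c`: earned potential `e ← min(e_max, e + r_earn·dt)`,
  wind rises by `w_gain·dt`.
* `φ` ∈ {inhale, pause}: speed `v ← max(v_min, v − k_dec·dt)`.
* `φ` = exhale: `v += a_basic·dt` unconditionally; if `c`, additionally
  `v += (a_small + (a_max_earned − a_small)·e/e_max)·dt` and the wind rises.
* `e` resets to 0 when an exhalation phase ends — the potential is earned
  for the *next* exhalation only and does not carry across cycles.
* Wind relaxes exponentially toward its baseline `w0` whenever breathing is
  not correct; wind is an output channel for a renderer and has no effect on
  the dynamics.
* distance `+= v·dt` with the post-update speed.

No published numeric values exist for these dynamics, so the defaults are
normalized units chosen around two anchors: `r_earn` = 0.25/s makes one full
correct 4-s inhalation exactly fill the cap `e_max` = 1, tying the fill rate
to the pattern; and the remaining values (`v_base` = 1, `v_min` = 0.2,
`k_dec` = 0.05, `a_basic` = 0.15, `a_small` = 0.05, `a_max_earned` = 0.6)
separate perfect from absent adherence by a wide margin (7489 vs. 138
distance units over 6 min) while keeping an exhale-only breather clearly
above the floor. Correctness drives the dynamics instantaneously per step —
real-time feedback cannot wait for a phase to finish — while full-phase
correctness is kept for reporting. Environment milestones are frozen at
25% / 60% / 85% of the perfect default session's distance (1872.2 / 4493.4 /
6365.6), encoding only the ordering of the landscape stages; later stages
are intentionally not guaranteed to be reached.

The countdown before the protocol is engine configuration (default 3 s); it
contributes no distance and no schedule intervals.

## Synthetic physiology

The generator emulates the *structure* of a 16-subject within-subject study,
not any particular cohort's magnitudes. Per subject profile: adherence
probability (default 0.9, surfaced in the study manifest, never hard-coded),
onset latency (0.1–0.5 s), spontaneous breathing rate (~N(12, 1.5)
cycles/min), mean heart rate (~N(72, 8) beats/min), beat-to-beat jitter
scale (25 ms) and respiratory amplitude (~N(5, 1.2) V).

Breath streams: per paced cycle a Bernoulli(adherence) draw decides whether
the subject reproduces the cycle's phases shifted by their latency; runs of
non-adherent cycles are filled with spontaneous breathing at the natural
rate (3% cycle-length jitter, 4:2:4 phase proportions). Filling whole runs
rather than each 10-s span separately avoids artificially restarting a
breath at every cycle boundary, which would inflate the apparent breathing
rate.

Respiration: raised-cosine ramps per phase (rise over inhale, fall over
exhale, hold elsewhere), preserving the 4-s/2-s inhale/exhale asymmetry;
peak-to-trough equals the profile amplitude.

Heartbeats: IPFM. The instantaneous rate is
`m(t) = (HR/60)·(1 + g·r(t)) + η(t)` with `r(t)` the respiration centred on
its mean and scaled so its largest excursion is 1 — centring keeps `HR` the
true mean rate despite the asymmetric waveform — and `η` an AR(1) process
(1-s correlation time) whose stationary scale maps the profile's
interval-domain jitter into rate units via `δm ≈ δrr·m²`. The rate is floored
at 5% of baseline; a beat fires at each integer crossing of the trapezoidal
running integral of `m`. RSA depth defaults: `g` = 0.05 at baseline and 0.12
in both paced conditions — slow breathing deepens RSA, and the equal paced
depths encode, in the generative truth, that the two trainings are
physiologically equivalent. The jitter scale puts baseline RMSSD in the tens
of milliseconds, the right order for resting adults, without claiming to
reproduce any specific cohort.

Randomness is hierarchical (`SeedSequence` spawning per subject, condition
and signal), so any single recording can be regenerated in isolation from
the master seed. Baseline always comes first — it is a resting measurement —
and the two trainings follow in per-subject randomized order; the washout
between conditions leaves no data artifact.

What the generator does *not* model: ECG morphology and beat detection,
ectopic beats and artifacts, slow non-respiratory rhythms (Mayer waves
beyond the AR(1) jitter), drifting adherence within a session, and
belt-signal noise. Passing tests therefore show that the pipeline recovers
the physiology this model encodes, not that the effect sizes match any real
cohort; frequency-domain magnitudes in particular are not comparable to
recordings from hardware.

## HRV measures

Time domain on the raw interval series: IBI = mean, HR = 60000/IBI (a
deterministic choice on short records; beat counting would differ only via
edge effects), SDNN = sample (n−1) SD, RMSSD, and pNN50 with a *strict*
"> 50 ms" — a series of exactly-50-ms jumps scores 0.

Frequency domain: the interval series, attributed to each interval's ending
beat time, is cubic-spline resampled at 4 Hz, linearly detrended and passed
to a Hann-windowed averaged periodogram (120-s segments, 50% overlap;
interpolation + Welch is the de-facto standard for 5-min HRV windows). A
recording shorter than two segments falls back to a single full-length
segment. Band powers are trapezoidal integrals of the PSD over
VLF 0.0033–0.04, LF 0.04–0.15 and HF 0.15–0.4 Hz, in ms²; the LF/HF ratio is
reported as NaN when HF power is numerically zero. A Lomb-Scargle estimator
on the irregular beat times is available via `SpectralConfig(method=
"lombscargle")` for cross-checking band placement. No artifact or
normal-beat filtering is applied: inputs are assumed to be clean beat series
(documented limitation).

Respiration: band-limited to 0.05–1 Hz, cycle peaks detected with a
minimum-prominence rule (0.25 of the filtered SD, ≥1 s apart). The breathing
rate is 60 over the *median* peak-to-peak interval — the median instantaneous
respiratory rate. The median is preferred over dividing the peak count by
the duration because a subject who briefly drops out of pacing breathes a
few fast spontaneous cycles; a count-based rate jumps to ~6.6/min at 90%
adherence while the paced rhythm is plainly 6/min, and the median reflects
that (the count-based variant remains available as `cycle_count_bpm`). ARA
is the mean peak-to-trough amplitude between consecutive detected peaks, in
volts. A flat signal reports rate 0 and amplitude 0 rather than an error.

One measurement artifact worth knowing: paced exhalations always return the
rendered waveform to its trough, whereas truncated spontaneous cycles may
not, so measured ARA can differ slightly but systematically between paced
and baseline recordings even though the generative amplitude is identical.

## Statistical plan

Per measure: condition descriptives (mean, sample SD, median, quartiles by
linear interpolation), then a Friedman omnibus on the n × 3 table using
within-subject mid-ranks and the tie-corrected statistic
`Q = (k−1)·Σ_j (R_j − n(k+1)/2)² / (Σ r² − nk(k+1)²/4)`, chi-square with
k−1 df. Measures with omnibus p < α (default .05) proceed to the three
pairwise signed-rank comparisons CIRCLE−BASELINE, BREEZE−BASELINE,
BREEZE−CIRCLE.

Wilcoxon signed-rank: zero differences are excluded before ranking (the
convention consistent with reconstructing effective sample sizes from
printed W/rbc pairs), mid-ranks on |d|, W reported as min(W⁺, W⁻). The p is
exact — the null distribution of W⁺ built by convolution over all 2ⁿ sign
assignments — whenever |d| is tie-free and n ≤ 20 (the cutoff is a
documented choice; enumeration is cheap there and ties force the
approximation anyway); otherwise a normal approximation with tie-corrected
variance and no continuity correction (a config flag adds it). Effect size
is the rank-biserial correlation `(W⁺ − W⁻)/(W⁺ + W⁻)`, which satisfies
`|rbc| = (S − 2W)/S`, `S = n(n+1)/2`, when all differences share a sign. In
the pipeline report a comparison whose differences are all zero is emitted
as a degenerate row (NaN statistics) rather than aborting the analysis.

No multiple-testing correction is applied by default; Holm step-down is
available via a flag. Cohen's κ uses product-of-marginals chance agreement
and is NaN in the degenerate `p_e = 1` case.

These statistics are implemented in-package because the required reporting
conventions (min-sum W, rank-biserial, the exactness cutoff, tie-corrected
Friedman) are not exposed together by a single library routine; the test
suite cross-checks them against `scipy.stats.wilcoxon`,
`scipy.stats.friedmanchisquare` (tie-free cases) and
`sklearn.metrics.cohen_kappa_score`, and against brute-force sign
enumeration.

## Problem sizes and numerical choices

The default study is 16 subjects × 3 conditions × 6 min, with respiration at
8 Hz and the engine at 20 Hz; a full simulate-and-analyze pass takes well
under a second. The type-I-control check simulates 500 null studies (three
identically generated spontaneous conditions per subject) and verifies the
Friedman rejection rate at α = .05 lies in [0.02, 0.08], a band fixed in
advance from the binomial standard error at 500 replicates plus slack for
the chi-square approximation at n = 16. Property tests are derandomized so
runs are reproducible.

Degenerate inputs are handled explicitly rather than propagated: empty
schedules produce empty sessions with distance 0; flat respiration yields
zero-rate metrics; an all-zero difference vector is an error at the
single-test level and a flagged row at the pipeline level; non-finite engine
state raises immediately.

## Known limitations

* Engine dynamics magnitudes are design choices in normalized units; only
  their structure (what accelerates, decays, caps and resets when) is
  grounded.
* The physiology generator's effect sizes are set by the RSA-depth defaults;
  the pipeline's directional conclusions replicate by construction, which is
  the intended use (a test bench), not evidence about real users.
* Spectral magnitudes depend on the estimator configuration; only band
  *placement* and ordering are robust claims.
* The breathing-phase detector itself is out of scope: streams of
  already-classified phases are the input boundary.
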