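# breezesim

Slow-paced breathing training (≈6 breaths/min) raises heart-rate variability
(HRV) and induces relaxation, and gameful biofeedback — a sailboat whose wind
and speed respond to how well the user follows the pacing — can make such
training engaging enough to stick with. Evaluating a design like this needs
three things that are awkward to study together: the deterministic game
dynamics, the physiology they are meant to move, and the within-subject
statistics that decide whether they moved it. `breezesim` packages all three
as a renderer-free Python library, so the complete experiment — spontaneous
baseline vs. a standard paced trainer (CIRCLE) vs. the gameful trainer
(BREEZE) — can be simulated and analyzed end to end with no hardware and no
external data.

It is written for researchers and developers of breathing-training and
biofeedback applications who want a reproducible test bench for feedback
dynamics and analysis pipelines.

## What is inside

**Protocol & adherence.** A breathing pattern (default 4 s inhale, 2 s
exhale, 4 s pause ⇒ 6 cycles/min) is expanded into a schedule of half-open
phase intervals tiling a 6-min session. Detected phase streams are scored
against it by same-label overlap, distinguishing fully correct phases
(coverage ≥ 0.9) from fractional ones.

**Engine.** A deterministic time-stepped state machine: correct inhalation
charges an earned-acceleration potential `e ← min(e_max, e + r_earn·dt)`;
speed decays during inhalation/pause, `v ← max(v_min, v − k_dec·dt)`; every
exhalation adds a basic acceleration `a_basic`, and a correct exhalation adds
a bonus interpolating from `a_small` to `a_max_earned` with `e/e_max`;
distance integrates speed and maps onto environment milestones
(snowy → grassy → beach → open sea).

**Synthetic physiology.** Respiration is rendered from the phase stream as
raised-cosine segments; heartbeats come from an integral pulse frequency
modulation (IPFM) model with respiratory sinus arrhythmia:

    m(t) = (HR/60)·(1 + g·r(t)) + η(t),   beat when ∫m dt crosses an integer,

with `r(t)` the centred, unit-scaled respiration, `g` the RSA depth (larger
when breathing slowly) and `η` AR(1) jitter. Slow 6/min breathing places the
cardiac modulation in the LF band (0.04–0.15 Hz); spontaneous ~12/min
breathing places it in the HF band (0.15–0.4 Hz).

**HRV & statistics.** The 11 outcome measures (IBI, HR, SDNN, RMSSD, pNN50,
HF/LF/VLF power, LF/HF ratio, breathing rate, respiratory amplitude), then
the nonparametric plan: Friedman omnibus per measure (tie-corrected,
df = k−1), pairwise Wilcoxon signed-rank tests for significant measures
(zero-exclusion, mid-ranks, exact p for tie-free n ≤ 20, otherwise a
tie-corrected normal approximation), rank-biserial correlation
`rbc = (W⁺ − W⁻)/(W⁺ + W⁻)` as effect size, and Cohen's κ for coder
agreement.

## Worked example

```bash
python examples/03_full_study_report.py
```

simulates 16 subjects × 3 conditions and prints, among other measures:

```
measure      q  df     p  significant
   SDNN 24.125   2 0.000         True
  RMSSD 24.125   2 0.000         True

pairwise signed-rank comparisons for RMSSD:
condition reference  median_diff    w     p    rbc
   CIRCLE  BASELINE       10.697  0.0 0.000  1.000
   BREEZE  BASELINE        9.854  0.0 0.000  1.000
   BREEZE    CIRCLE       -0.869 36.0 0.105 -0.471

paced median breathing rate: 6.00 cycles/min
```

Read: both paced trainings raise RMSSD in every single subject (W = 0,
rank-biserial correlation 1.0 — the largest possible paired effect), the two
trainings do not differ from each other, and the pacer holds the breathing
rate at 6 cycles/min. `examples/01_protocol_and_session.py` shows the game
side: a perfectly followed session scores distance 7489.0 and reaches the
open sea, while an absent stream drifts 138.3 units and never leaves the
snowy start.

The other examples cover single-subject physiology synthesis and coder
agreement. The same workflows are available from a thin CLI
(`breezesim simulate-session | simulate-study | analyze | report | kappa |
demo`).

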