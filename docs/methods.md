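# Methods

## Cystometry metrics

The pressure channel is smoothed with a centred moving average over 0.1 s
(window = `round(0.1 × sampling rate)` samples: 50 at 500 Hz, 500 at
5000 Hz), with shrinking windows at the trace boundaries.  The derivative
used by the threshold rule is the first discrete difference of the
smoothed series; because the rule compares the derivative only to a
fraction of its own maximum, the per-sample vs per-second scaling is
irrelevant and the simpler per-sample form is used.  "First time reached"
is the smallest sample index with `d ≥ 0.65·max(d)` on the 20 s lookback
window (`≥`, so the maximal-derivative sample itself always qualifies);
the difference `d[i] = p[i+1] − p[i]` is assigned to the left sample.
P_thresh is read from the *raw* pressure at the threshold time.  A
lookback window that never rises (`max d ≤ 0`) leaves the cycle flagged
and excluded from threshold/volume summaries.

Cycle segmentation is not part of the metric definitions and had to be
chosen: candidate P_max events are peaks of the smoothed trace with at
least 5 cmH2O prominence and 10 s separation (both configurable); the
cycle start is the pressure minimum since the previous cycle's end; the
cycle is accepted only if that start lies within 5 cmH2O of the
recording-wide smoothed minimum (it rises *from baseline*) and the trace
returns to within 10 % of the peak prominence above the start level (it
returns *to baseline*).  SCI-style recordings — sustained high-pressure
oscillations whose troughs stay far above baseline — therefore yield an
empty cycle list and are summarised by the no-cycle path: subtract the
recording-wide minimum of the raw trace (the full provided trace,
including any pre-infusion samples), report the maximum of the normalised
series as P_max, and detect non-voiding contractions with the same peak
finder minus the baseline conditions (separation default 2 s, suited to
oscillation rates around 0.1 Hz).

Per-recording summaries average the first three complete cycles; fewer
are averaged as-is and flagged.

## EMG section energies

The EMG channel is band-pass filtered (zero-phase Butterworth order 4,
10–10000 Hz clipped below Nyquist) with a powerline notch (50 Hz default,
Q = 30).  Each contraction window (threshold to peak, padded by 25 % of
its span to push decomposition edge effects outside the partition) is
decomposed by empirical mode decomposition: cubic-spline envelopes
through the local extrema, mirror-extended (2 extrema reflected about
each boundary), Cauchy-type SD stopping criterion 0.2, at most 10
siftings per IMF and 10 IMFs.  The decomposition is complete by
construction (IMFs + residual sum to the input exactly).  Instantaneous
amplitude and frequency come from the analytic signal (Hilbert transform;
frequency as the gradient of the unwrapped phase).

The energy of a section is `Σ a²(t)·Δt / section duration` over the
samples (of all IMFs) whose instantaneous frequency lies in 0–500 Hz —
an energy *rate*, which makes the quantity independent of sampling rate.
"Before" and "after" are parts 1–2 and 4–5 of the same five-part
partition of [P_thresh, P_max]; only the middle part has an explicit
definition ("during voiding"), and symmetric flanks inside the partition
keep the three sections adjacent and non-overlapping.  Percentages are
computed from the duration-normalised energies first; rounding (half-up,
to integers) happens only at reporting time.  V-shape is a strict
comparison — ties are conservatively classed non-v-shape.  Zero-energy
contractions are excluded rather than given undefined percentages.

## The simulator

The generator is phenomenological: it reproduces the *features the
detector keys on*, not bladder biomechanics.

Voiding phenotypes (sham/pBOO) build each cycle as a compliance ramp
(default 0.08 cmH2O/s from a 10 cmH2O baseline) followed by a raised-sine
contraction pulse (default 20 cmH2O amplitude — 30 for the pBOO preset —
over 3 s) during which the accumulated ramp pressure is released
linearly, so every cycle ends exactly at baseline.  The pulse is smooth,
giving the 65 %-derivative rule a well-defined crossing whose analytic
solution is stored as ground truth.  The default cycle interval is 120 s:
compressed relative to real mouse filling times (minutes at 10 µL/min) to
keep recordings compact, while pressure amplitudes and contraction
dynamics stay realistic; filling volumes scale accordingly.  The SCI
phenotype ramps at 0.5 cmH2O/s to a plateau 25 cmH2O above baseline and
oscillates (raised-sine, 10 cmH2O at 0.1 Hz — free parameters, since only
"high-pressure oscillations" are described qualitatively); it never
returns to baseline and emits no voids.

EMG is Gaussian white noise band-passed to the carrier band (100–400 Hz
at 5 kHz presets), amplitude-modulated: constant (flat), suppressed to
`vshape_suppression_fraction` during the middle fifth of each
threshold-to-peak interval with 5 %-span raised-cosine shoulders
(v-shape), or scaled linearly with clean pressure normalised to the
active pressure range — plateau trough to peak for SCI, baseline to peak
for voiding phenotypes — rising from 0.2 to 1.2 (dyssynergic).  The
active-range normalisation makes sphincter activity track the
contraction's pressure excursion, which is the physiological picture of
dyssynergia; normalising over the whole-recording range would compress
the contrast into a few percent and make the planted label ambiguous.  A
burst modulation at 8 Hz (depth 0.5) adds motor-unit-like envelope
structure that averages out over the ≥ 0.3 s sections.  Additive noise:
0.2 cmH2O on pressure (0.05 in recovery studies, i.e. the low-noise
condition), 3 mV-scale sensor noise on EMG, optional powerline sinusoid.

The scale channel steps by the per-cycle infused volume at each void,
quantised to 5 Hz scale ticks; each void is omitted with
`void_trap_probability` (default 0.3), emulating voids trapped in the
animal's fur.  All randomness derives from one integer seed; identical
parameters give bit-identical traces.

What the simulator does **not** emulate: pressure–volume constitutive
behaviour, abdominal-pressure artefacts, movement artefacts, electrode
drift, non-stationary EMG spectra, or inter-animal variability in cycle
timing.  Passing recovery tests therefore demonstrate correctness of the
detection rules under the stated signal model, not robustness to every
artefact of live recordings.

## DEG comparison

`filter_degs` applies exactly one p-statistic criterion (raw or adjusted)
per call, matching the three named presets (`pboo_inclusion` p < 0.1,
`sci_inclusion` adj-p < 0.1, `volcano_strict` adj-p < 0.05 and
|log2FC| > 0.5), which are kept separate rather than reconciled.
Fractions are reported over genes with nonzero mean counts, rounded to
two decimals (trailing zeros dropped in display: 0.7999 → 0.8).
Concordance is the sign product of the two log2 fold changes; an exact
zero is classed discordant with a warning.  Simulated DEG tables plant
tiny p-values and |log2FC| ≥ 0.75 for significant genes and near-zero
fold changes for null genes (uniform p-values, Benjamini–Hochberg
adjusted), so planted set structure is recovered exactly under the strict
preset.

## Cohort statistics

Group summaries report mean ± sample SD (n−1 divisor).  Cross-sectional
contrasts use Welch's unpaired t-test (Student optional) of each disease
group against sham with Bonferroni multiplication capped at 1;
longitudinal effects use one-way repeated-measures ANOVA with subject as
block (statsmodels `AnovaRM`) plus Bonferroni-corrected paired t-tests,
with listwise deletion (and a warning) for subjects missing weeks.
Integer percentages use half-up rounding.

## Problem sizes and numerical choices

Recovery studies use 20 seeds per condition with 3 cycles per sham
recording and 120–190 s SCI recordings; the brute-force threshold oracle
runs 1000 random 25 s windows at 50 Hz; the null calibration runs 2000
replicates of n = 10 per group.  These sizes give stable rates while
keeping the whole suite and the acceptance script in the minutes range
on one CPU.  Tolerances: threshold recovery within 0.2 s (twice the
smoothing window), simulated-plateau P_max within 1 cmH2O (extreme-value
range of the smoothed noise), EMD tone recovery within 5 Hz / 10 %
amplitude, reconstruction residual below 1e-6 of the signal range.
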