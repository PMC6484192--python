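# Methods

## Model and procedure

The pipeline analyses one extracellularly recorded unit per session under an
acute-injection design: 900 s of baseline, injection, 6300 s of follow-up
(7200 s total). Its statistical object is the 60-s-bin PSTH of firing rate;
the 1000-ms acquisition series is retained as the raw record (summing 60
consecutive 1-s bins reproduces the matching 60-s bin exactly — an invariant
the tests enforce).

Response detection is the baseline-band rule: with baseline mean rate
`m` and sample SD `s` (n−1 denominator, over the 15 pre-injection bins), a
unit is excitatory/inhibitory when at least `run_length = 3` consecutive
post-injection bins lie strictly above `m + 2s` / strictly below `m − 2s`.
Strict inequality is used because the criterion is deviation *beyond* the
two-SD band. Both directions use the same rule (assumed symmetric); when runs
of both signs occur the earlier one determines the label and both are kept in
the output. Onset latency is the start time of the first qualifying run minus
the injection time, in minutes; percent change averages the rate over the
qualifying-run bins only (an option to average all post-onset bins instead
would be a one-line change, but onset-locked averaging matches how graded
responses are usually quoted).

Group inference is a paired Student t test on per-neuron (baseline mean,
post-injection mean) rate pairs, df = n − 1, two-tailed, α = 0.05, no
correction across dose groups. The "post" mean deliberately covers the full
105-minute window, not just response bins, since the comparison is
"after injection vs baseline activity". Differences are post − baseline, so
excitation yields positive t; reports that take them the other way round
(as SPSS-style pre−post output does) flip the sign, which affects nothing
two-tailed. Published group dfs in this literature are not always consistent
with the printed group sizes; this implementation always reports df = n − 1.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `injection_time` | 900 | s | 15-min baseline protocol |
| `session_duration` | 7200 | s | 120-min session |
| `psth_bin_width` | 60 | s | the rule's "points" are 60-s bins |
| `acquisition_bin_width` | 1.0 | s | stored acquisition record |
| `k_sd` | 2.0 | baseline SDs | two-fold-SD band |
| `run_length` | 3 | bins | three consecutive points |
| `sd_floor` | 1/60 | spikes/s | see degenerate baselines |
| `pyramidal_cap` | 8.0 | spikes/s | inclusive "eight spikes or less" filter |
| `min_snr` | 2.0 | — | unit isolation criterion, strict ">" |
| `threshold_k` | 4.0 | noise SDs | detection threshold |
| `dead_time` | 1.0 | ms | merges biphasic lobes / doublets |
| `refractory` (simulator) | 2.0 | ms | physiological floor |

The baseline SD is computed over 60-s PSTH bins, not 1000-ms bins: the
classification rule operates on PSTH points, and a 1-s-bin SD (≈ √rate) would
widen the band several-fold and destroy sensitivity. This is a declared
convention; the alternative can be obtained by passing a 1-s PSTH to
`baseline_statistics`.

## Synthetic data: what it emulates and what it does not

Each unit is an inhomogeneous Poisson process with an absolute refractory
period, simulated by thinning a dominating homogeneous process at the rate
maximum and then greedily deleting sub-refractory spikes. Thinning is exact
for the piecewise-linear rate profiles used (step, or linear ramp over
`ramp_duration`; a zero-length ramp consumes the identical random stream as
the step, so the two are bitwise equal under one seed). Dead time imposes the
standard rate compression λ/(1 + λr): a nominal 11.2 spikes/s step is observed
at ≈ 10.95 spikes/s, and a nominal +180 % effect is recovered as ≈ +176 %.
Closed-form Poisson checks in the tests therefore set `refractory = 0`; the
dead-time-corrected expectation is tested separately.

Group presets encode the reported response structure: per-group unit counts
(15/16/14/16), percent-change strata (e.g. +100–115 % ×3, +160–180 % ×4,
+346 % ×1 and one 80 % reduction for the mid dose; +120–190 %, +240–270 %,
+310–420 % and two 55–65 % reductions for the high dose), and uniform onset
windows (47–56, 47–64, 47–56, 42–61 minutes post-injection). Within-range
distributions are uniform — only ranges are reported, and uniform is the
least-informative choice consistent with them. The low-dose group's effect
magnitudes are unreported; the saline-group magnitudes (+25–70 %, −60–70 %)
are used as the nearest stated analogue. Baseline rates are drawn uniform on
2.0–7.5 spikes/s: below the 8 spikes/s pyramidal cap by a margin, because a
*true* rate at the cap would put the measured 15-min baseline above it in
about half of sessions through counting noise alone, silently excluding
simulated pyramidal units. Cohort seeding fans a single seed into per-unit
`SeedSequence` substreams keyed by unit index, and each unit's own
ground-truth config carries a derived seed, so units regenerate independently.

Not emulated: bursting and serial ISI correlations, rate drift and
non-stationary baselines, waveform shape changes, electrode drift, overlapping
units, and pharmacokinetic ramp-up (onset is a step by default; the ramp
option exists but the presets do not use it). Passing recovery tests on this
generator therefore demonstrates the *rule's* behaviour under its own
idealised assumptions, not robustness to real-data pathologies.

## Detection stage

The synthetic voltage is a one-cycle-sine biphasic template (positive peak at
the spike time) on white Gaussian noise; constructed SNR = peak amplitude /
noise SD. Detection uses |x| thresholding so negative-going spikes follow the
same path; event time is the excursion's peak sample (stable under noise,
unlike the first crossing). End-to-end fidelity is quantified at constructed
SNR 6, 10 kHz, 8 spikes/s, with the height window (5, 12) noise-SDs engaged:
bare 4-SD thresholding alone leaves ~6 noise excursions per 10-s trace
(expected from the Gaussian tail), and it is the window discriminator —
integral to this detector as in the hardware it mirrors — that removes them,
giving recall and precision above 0.99 at ±1 ms matching. Recovery tests use
±1 ms tolerance, one waveform width.

## Numerical choices and degenerate inputs

- Bins are half-open [t, t+Δ) on a 0-based session clock; a spike exactly on
  an edge belongs to the right bin. Trailing partial bins are dropped and the
  spikes in them reported (`n_dropped_spikes`), never silently lost.
- A zero-variance baseline (e.g. a silent cell) would make the band
  degenerate; the SD is floored at 1/60 spikes/s — one spike per PSTH bin, the
  resolution of the rate measurement — so a silent-then-active neuron is
  classifiable. Such units are flagged and excluded from group tests.
- Zero-variance paired differences yield a flagged degenerate t result
  (t, p = NaN) rather than an exception, so batch pipelines can report them.
- Units with no detected events have undefined SNR (NaN) and are excluded
  with an explicit reason.
- Timestamp files store full-precision `repr` floats, so write→read
  round-trips are bitwise exact.

## Known limitations

- The band rule's false-positive rate is substantial by modern standards:
  with the SD estimated from only 15 bins, ~4–5 % of truly null units acquire
  a qualifying 3-bin run somewhere in 105 post-injection bins (simulation
  estimate; the tests pin it below 10 %). Consequently an exact
  count-by-count recovery of a 16-unit cohort's (10, 2, 4) class structure
  occurs in only ~3 out of 4 seeded cohorts even though true effects are
  recovered at ≳ 99 %. This is a property of the rule itself — real studies
  using it report nonzero "responders" to vehicle injections — and the
  package reports it rather than papering over it.
- "Earlier run wins" means a pre-onset false run can mislabel a genuinely
  inhibitory unit; both run lists are retained in the output for audit.
- No multiple-comparison correction across groups, mirroring the analysis it
  implements; add one downstream if comparing many doses.
- Onset resolution is one PSTH bin (1 min); sub-bin onsets and slow ramps blur
  across bins.

## Problem sizes in the validation suite

Monte-Carlo checks use 1000 random PSTHs for oracle agreement, 200 simulated
sessions for effect/onset recovery, 500 null cohorts of 16 units for type-I
calibration, 100 ten-second traces for detection fidelity, and 60–100 cohorts
for count recovery; these sizes put binomial uncertainty comfortably inside
each asserted bound.
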