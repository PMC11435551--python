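# Methods

This note documents the models, estimators, defaults and design decisions
behind `insolegait`, and states what the synthetic-data tests do and do not
show about real recordings.

## Device and signal model

The modelled insole carries 18 capacitive pressure cells (grouped here as
6 heel / 6 midfoot / 6 forefoot), each digitized to 8 bits and sampled at
110 Hz. Working channels:

* **counts** — the integer cell sums used for event detection (the
  threshold constants 0.2 / 50 / 30 live on this scale);
* **pressure** — calibrated kg·cm⁻² per cell; summed over the 18 cells it
  approximates the vertical ground-reaction force and feeds the mean-force
  parameter and the stance-normalized curves. The exact manufacturer
  normalization from 18 cells to kg·cm⁻² is not published; a configurable
  `force_normalization` divisor (default 1.0) maps the summed pressure onto
  the conventional 8–9 kg·cm⁻² single-stance scale.

## Event detection

With S the summed signal and dS/dt its first difference per sample:

* **Initial contact** at the first sample t of a rising episode with
  dS/dt(t) > 0.2 and S(t + L) > 50;
* **Toe-off** at the first sample t of an unloaded episode with S(t) < 30
  and S(t + L) < 30;

where L is 100 ms (exactly 11 samples at 110 Hz; other rates round to the
nearest sample). Like events closer than 100 ms are debounced, the final
look-ahead window of a trial cannot host detections, and a state machine
enforces strict IC/TO alternation, counting discarded candidates (the
second load peak of a normal stance re-triggers the IC predicate roughly
once per cycle; alternation removes these deterministically).

Numerical choices worth stating:

* **Derivative scale** is signal units per *sample*, not per second: on the
  count channel a per-second scale would let quantization flicker cross the
  0.2 threshold at every frame.
* **Smoothing placement.** A Savitzky–Golay filter (window 11, polynomial
  order 3) is part of the detection configuration but is *off* in the
  detection path by default (`smooth_detection_channel=False`). A symmetric
  11-sample window leaks a sharp stance onset ~3–5 samples backwards
  (negative edge coefficients produce a small positive "pre-ring" in the
  smoothed derivative), which biases initial contacts early by up to ~30 ms.
  Keeping the detection channel unsmoothed preserves one-sample timing; the
  smoothed sum is still used for the force channel, where edge fidelity
  matters less than noise suppression. The flag restores the smoothed
  detection variant for sensitivity analyses.
* Timing convention: an event at continuous time τ is detected at the first
  sample index ≥ τ, so detected events sit within one sample of truth.

## Cycle parameters

A cycle is IC → next ipsilateral IC; the first and last cycles of every
trial are discarded (edge effects, incomplete contralateral coverage).
Double support is the Lebesgue measure of the stance interval intersected
with the contralateral stance intervals — the sum of both sub-periods, the
reading consistent with double-support values near 40 % of stance. Single
support is attributed to the supporting foot as stance − double; the
identities single + double = stance and stance + swing = cycle therefore
hold to machine precision on every processed cycle and are asserted at run
time. Cycles with contralateral coverage gaps or empty single-support
intervals are flagged and excluded, never imputed.

Force curves are normalized over **stance** (not the whole cycle, where the
signal is identically ~0 in swing) by linear interpolation onto 101 even
fractions; 101 and the stance convention are configurable.

## Reliability and responsiveness estimators

* **SEM** = √( Σᵢ σᵢ²/n ) over the n = 3 trials of a condition, where σᵢ²
  is the *sample* variance (denominator nᵢ − 1) across the cycles of trial
  i — the denominator convention is our choice. For the force signal the
  SEM is computed at each of the 101 grid instants and averaged.
* **MDD95** = 1.96·√2·SEM, a fixed ratio of 2.771859… checked to machine
  precision.
* **ICC(3,k)** = (BMS − EMS)/BMS from the two-way rows × trials ANOVA.
  Rows are cycle indices truncated to the common cycle count across the
  three trials; this unit of analysis is a design decision isolated in
  `ConditionDataset.parameter_matrix` so alternatives (e.g. per-minute
  means) can be plugged in. Incomplete rows are deleted listwise, with a
  configurable ceiling (10 %) on the incomplete fraction.
* **Effect size** = (x̄_asym − x̄_without)/σ_without, signed; means and SDs
  pool all cycles of a condition's three trials.
* **Classification bins** are closed on the lower edge of the higher
  category (ICC 0.80 → "very good", |ES| 1.2 → "very large"); the
  conventional strict inequalities leave boundaries unassigned, so the
  tie-break is ours and is documented here.
* **Aggregation**: per parameter, reports carry the smallest and largest
  cell across feet; the single MDD row uses the larger of the two feet's
  SEMs; the pooled induced-asymmetry column uses the maximum SEM over the
  six asymmetric conditions; effect sizes are computed per asymmetric
  condition against both baselines (overground and symmetric treadmill)
  and the extremes reported. Percentages (SEM%, MDD%) use the mean of the
  same (parameter, foot, condition) cell as denominator, computed from
  unrounded values internally; the display formatter computes the percent
  from the display-rounded value, which is how the reference tables were
  evidently typeset (0.86/8.13 → 10.58 %).

## Synthetic-data generator

The generator defines the study conditions: 8 named walking conditions
(overground; symmetric treadmill at 1.2 m/s; ±16/33/50 % split-belt), 3
trials each, 6-minute trials by default. Timing model, per trial:

* shared stride clock: both feet share one stride period per cycle, the
  contralateral IC offset by `interfoot_phase` (default 0.5);
* stride 1.145 s and stance fraction 0.635 at 1.2 m/s — a healthy adult's
  values, giving stance ≈ 63 % of cycle and double support ≈ 27 %;
* stride shortens with mean belt speed as (1.2/v̄)^0.3; each foot's stance
  fraction falls by 5 % of itself per m/s of *maximum* belt speed (this is
  what shrinks double support for both legs); the driven foot additionally
  loses stance in proportion to the speed ratio (gain 0.20), sized so the
  50 % condition shortens driven stance by ~70–120 ms — the published
  order of magnitude, not a fitted value;
* per-cycle stride/stance draws = condition mean + trial effect
  (between-trial SD: 4 ms, force 0.05 kg·cm⁻²) + step noise (within-trial
  SD: stride 8 ms, stance 10 ms, force 0.15 kg·cm⁻²) + a slow within-trial
  drift (6 ms peak-to-peak) that repeats across trials, standing in for
  accommodation trends; the overground condition doubles all SDs;
* each stance renders as a double-bump summed-pressure profile
  (sin^0.6(πu) with a Gaussian mid-stance trough of depth 0.25, peak
  10.5 kg·cm⁻² → single-stance mean ≈ 8.3), distributed over the cells by
  heel → midfoot → forefoot Gaussian envelopes; swing frames are zero;
* sensor noise is contact-proportional (relative SD 0.02): an unloaded
  capacitive cell reads a clean zero after 8-bit quantization, so swing is
  silent — this is what makes one-sample event recovery possible and is
  realistic for this sensor class;
* 8-bit counts = pressure quantized at 2.5 kg·cm⁻² full scale per cell.

Identical config + seed give bit-identical output; trials draw from
deterministic child streams of the config seed.

**What passing tests show — and do not.** The generator reproduces the
protocol's geometry, variance structure and the split-belt directional
response, so tests demonstrate that the pipeline recovers known truth under
those conditions. It does not model turning (the overground condition is
treadmill-like with inflated variance), fatigue beyond a linear drift,
inter-subject variability, or biomechanically validated force profiles —
the published profiles for this sensor class are themselves not
representative of force-platform curves. Raw-data-dependent published
values (per-condition SEM/ICC magnitudes, the effect-size census
percentages) are therefore *not* reproduction targets; the package's
checks rest on closed forms, hand-computable examples and recovery of
injected truth.

Two structural points deserve emphasis:

* Under a shared stride clock, a shorter driven-leg stance forces a
  *longer* driven-leg swing (swing = stride − stance), so a per-leg swing
  reduction cannot occur in any steady-state split-belt simulation; the
  directional tests assert the stance, single-support and double-support
  signs only.
* Synthetic ICC(3,k) values on cycle-paired trials are low by construction:
  consecutive-cycle pairing carries little shared row structure beyond the
  drift term. The ICC estimator itself is validated against an independent
  ANOVA oracle and the closed-form population value of the explicit
  two-way model (σ_s²/(σ_s² + σ_e²/k)).

## Problem sizes

The test suite simulates 75 s trials (~63 cycles/foot) for recovery tests,
360 s (~312 cycles) for variance-calibration checks, and 40 s trials for
the eight-condition study; the acceptance script uses the same sizes plus
500 × 3 and 200 × 3 parameter tables and 3 × 1000 force curves. These sizes
give comfortable statistical margins for every tolerance while keeping a
full run in seconds; the 6-minute default remains the package's study
geometry.

## Known limitations

* The recording CSV dialect is this package's own documented stand-in; the
  proprietary export format of the real device is not parsed.
* Threshold units on calibrated-pressure-only recordings fall back to the
  pressure scale, where the published constants are almost certainly on
  the count scale; supply counts or adjust `DetectionThresholds`.
* Detection assumes clean swing unloading; dragging gaits that never drop
  the summed signal below the toe-off threshold would lose cycles (they
  are counted in diagnostics, not silently dropped).
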