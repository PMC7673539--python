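# Methods

This note documents the model as implemented, the parameter choices,
the synthetic stimuli, and the numerical decisions a maintainer or
reviewer would want spelled out.

## Model definition

**Input.** A strictly increasing sequence of onset times (r_i), in
milliseconds. All internal computation is in float64 ms; unit
conversion happens only at file I/O. Duplicate onset times are
rejected rather than merged — the matching step assumes distinct event
times, and coincident-event merging is a preprocessing concern.

**Hypotheses and projection.** A tactus hypothesis is an isochronous
pulse (ρ, δ); its projection is p_k = ρ + kδ for integer k (negative k
extends backward from ρ), restricted to the passage. Projection bounds
are inclusive with an absolute tolerance of 1e-6 ms: a beat that
coincides with the window edge under floating point must count as
inside (the worked example's third beat falls exactly on the final
onset).

**Congruency score.** For a hypothesis scored at time *now*, beats,
hits and onset counts are all taken inside the context window
[max(first onset, now − W), now] with W = 6000 ms. Each projected beat
is matched to its nearest onset in the window, ties toward the earlier
onset. hits = Σ 0.01^(|p_k − r_k|/δ), and

    score = (hits / #beats) · (hits / #onsets),

clamped to [0, 1]. Windowing all three terms keeps the score a proper
ratio when the passage outgrows the window. Two clamping-adjacent
details are deliberate: several beats may share one nearest onset
(nothing in the formula forbids it), which can push hits/#onsets
marginally above 1 — hence the clamp; and a hypothesis with no
projected beat in the window scores 0 rather than erroring, so every
live tracker has a score at every step.

**Correction.** At every onset each tracker refits its parameters by
ordinary least squares of the corrected prediction error

    ce_k = m (r_k − p_k) d^(|p_k − r_k|/δ),  m = 2, d = 1e-4,

against the *integer beat index* k, over the same 6 s window. The
abscissa choice matters: regressing on k (not on the beat time) makes
the slope directly a period correction in ms/beat and the intercept
(at k = 0, i.e. at ρ) a phase correction, so the corrected hypothesis
is (ρ + intercept, δ + slope). The regression is unweighted — the decay
term in ce already down-weights far matches. Fewer than two windowed
beats → zero correction (a line needs two points). A corrected period
that would be ≤ 0 is clamped to the smallest positive float and logged;
this only occurs on adversarial inputs. One correction is applied per
tracker per onset, with no inner iteration: repetition across onsets is
what separates real timing drift from beats that have no matching
onset (a single fit deliberately under-corrects because of the
attenuation).

The attenuated error is maximal at distance δ/ln(1/d) ≈ 0.109 δ and
essentially zero by half a period (|ce| ≤ 0.01 δ), which is what makes
the fit ignore unmatched beats.

**Main loop.** Per onset, in order: spawn → correct → score → collapse.
New trackers are corrected and scored at their creating onset, so the
first recorded state of a tracker already carries a score (and carries
the raw generated parameters exactly when the first correction is the
identity, as on perfect data). Recorded states hold post-correction
parameters. Only onsets at times ≤ the current onset are ever
consulted, so tracking a truncated input reproduces a prefix of every
surviving history bit-for-bit; the whole pipeline is deterministic.

**Similarity collapse.** Two hypotheses are duplicates when their
periods differ by ≤ 2% of the mean period *and* their phases, reduced
modulo the mean period, differ circularly by ≤ 2% of it. The oldest
tracker of a duplicate class survives (creation order; ties broken by
lower (a, b)); the newer one is discarded entirely, histories are not
merged. The 2%/2% thresholds are this package's choice (configurable);
no reference values exist for them. They keep the live population
sub-quadratic on isochronous input while never collapsing genuinely
distinct metrical levels (a 500 vs 1000 ms period differs by 66% of
the mean). An optional `max_trackers` score-based pruning exists for
very long inputs; it is off by default and logged when active.

## Derived outputs

**Clarity.** The clarity curve is the top score per processed onset
(ties toward the older tracker); overall clarity is its arithmetic
mean.

**Naive beat track.** Walking the onsets in order, the half-open
segment [r_t, r_{t+1}) is owned by the hypothesis that was top once r_t
was processed (post-update parameters), and its projected beats inside
the segment are emitted; the final segment closes at the last onset.
Emission is purely predictive — beats are never snapped to onsets,
because onset information may only be used after it is heard. Because
beats typically coincide with onsets, segment-ownership boundaries are
drawn 10 ms before each onset: otherwise sub-millisecond parameter
wobble between consecutive states decides, knife-edge, whether a seam
beat is emitted twice or not at all. Residual duplicates closer than
the same 10 ms are merged keeping the earlier beat.

**Adapted beat track.** Two modifications aimed at plausible tapping:
(i) the working period is doubled, repeatedly if needed, until it
exceeds 375 ms (≤ 160 bpm; a single doubling is not always enough —
187 ms only reaches 374 ms); when doubling, the emitted phase is chosen
among the undoubled grid's offsets ρ + jδ to minimize the mean distance
to the last emitted beats, preserving continuity across adoptions;
(ii) a challenger tracker replaces the incumbent only after strictly
outscoring it at every update for more than 3000 ms of onset time — any
lapse or change of challenger restarts the clock. Beats that would land
within 375 ms of the previously emitted beat (possible at adoption
seams) are dropped, so the adapted track's inter-beat interval always
exceeds the tapping floor.

## Synthetic stimuli

The generators emulate the canonical probe passages:

- **isochronous(n, ioi, phase)** — the reference pulse.
- **period_change** — n1 = 12 onsets at 500 ms, then n2 = 24 at 250 ms:
  an isochronous passage that becomes twice as fast in its second half.
- **phase_change** — 30 onsets at 500 ms; at 1/3 and 2/3 of the passage
  all later onsets shift forward by half a period. Two half-period
  jumps restore the original phase class without time running
  backward.
- **rallentando** — geometric IOI growth, IOI_k = ioi0 · factor^k, with
  n = 30, ioi0 = 400 ms, factor = 1.01. One percent per onset (a 1.32×
  slowdown overall) is a musically plausible closing rallentando and
  produces the expected dynamics: the incumbent hypothesis is
  progressively corrected and keeps the lead through the first half of
  the passage, losing it only in the second half. Steeper factors
  (e.g. 3%/onset, a 2.3× slowdown) out-run the per-onset correction
  and force an early hypothesis change instead.
- **mixed_patterns** — five subpatterns over a 500 ms tactus
  (isochronous; 250-250-500; 375-375-250, the 3-3-2 "tresillo";
  500-1000; 250-250-250-750), each repeated 4 times. Several are not
  isochronous, so overall clarity is strictly below a plain pulse's.
- **jitter** — seeded i.i.d. uniform ±A perturbation per onset,
  A < min IOI/2 so ordering cannot break; used for parameter-recovery
  tests (±2% of the IOI).

What the generators deliberately do *not* emulate: real performances'
correlated (drifting) timing noise, tempo curves other than geometric,
simultaneous voices, or onset-detection errors from audio. Passing
tests on these stimuli therefore show that the machinery behaves as
specified under controlled conditions, not that it matches human
tapping on real music — the latter requires annotated audio corpora
that are out of scope here, along with audio onset detection and the
standard beat-metric suites.

## Problem sizes and tolerances

The test suite and acceptance script use passages of 5–53 onsets —
enough for every behavior of interest (the context window covers at
most ~12–24 onsets at typical tempi, so longer passages only repeat
steady state). Oracle-equivalence checks run a few hundred randomized
small instances at 1e-9 relative tolerance against brute-force
enumeration (projection by exhaustive k-scan, matching by linear
search, regression by explicit normal equations). The worked-example
scores are asserted to six significant digits, the display precision
of the state table (`%.6g` formatting throughout).

## Known limitations

- Score and correction share a single context-window parameter; the
  model offers no recency weighting inside the window.
- Near window edges the windowed-count score oscillates slightly as
  beats and onsets enter/leave the window (visible as a ±0.04 ripple in
  the clarity curve right after a tempo change); this is inherent to
  hard windowing.
- The similarity test compares phases modulo the *mean* period of the
  pair, which for near-equal periods is exact but for periods near the
  2% boundary is an approximation.
- `OnsetSequence` requires strictly increasing times; simultaneous
  events (chords) must be merged upstream.
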