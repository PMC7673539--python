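# tactus

Causal, agent-based beat tracking and pulse-clarity estimation for
**symbolic onset sequences** — rhythm as a list of event times, with no
audio involved.

The package is aimed at researchers in music cognition and rhythm
perception who want an *inspectable* model of beat induction: not just a
beat track, but the full evolution of every competing beat
interpretation over time, including how strongly each one is felt
(pulse clarity) and when the dominant interpretation changes.

## The model

The input is a sequence of onset times (r_i) in milliseconds. A *tactus
hypothesis* is an isochronous pulse h = (ρ, δ) — phase and period —
whose projection is the beat grid

    p_k = ρ + k·δ,  k ∈ ℤ,

clipped to the heard passage. Each hypothesis lives inside an agent (a
*hypothesis tracker*) that records its parameters and score after every
onset. Processing one onset does four things, using only information up
to that onset (the model is causal):

1. **Spawn** — every earlier onset r_a paired with the current onset
   r_b defines a candidate hypothesis ρ = r_a, δ = r_b − r_a, kept when
   187 ms ≤ δ ≤ 1500 ms (320–40 bpm).
2. **Correct** — each tracker refits its parameters against the last
   6 s of onsets by ordinary least squares on the *corrected prediction
   error* of its beats,

       ce_k = m · (r_k − p_k) · d^(|p_k − r_k| / δ),

   with m = 2 and d = 10⁻⁴; the attenuation makes beats with no nearby
   onset contribute ≈ 0, so only genuine timing errors drive the fit.
   The fitted slope corrects the period, the intercept the phase.
3. **Score** — the *congruency score* of a hypothesis is precision ×
   sensitivity of its windowed projection against the windowed onsets:

       score = (hits / predictions) · (hits / music events),
       hits  = Σ_k 0.01^(|p_k − r_k| / δ),

   where each beat is matched to its nearest onset. The score is
   bounded in [0, 1]; 1 means every beat falls on an onset and every
   onset on a beat.
4. **Collapse** — trackers with similar period and the same relative
   phase are duplicates; the oldest survives.

The top score at each step is the **pulse-clarity signal**; its mean is
the passage's overall clarity. Projecting the top hypothesis segment by
segment yields a **beat track**, either naively or with two adaptations
toward plausible tapping behavior: the working period is doubled until
it exceeds 375 ms (≤ 160 bpm), and a challenger hypothesis is adopted
only after outscoring the incumbent continuously for more than 3 s.

## Worked example

Five onsets at a perfect 500 ms pulse, shifted by 1.04167 ms:

```sh
$ tactus generate isochronous --n 5 --ioi 500 --phase 1.04167 -o onsets.txt
$ tactus track onsets.txt -o table.csv
overall_clarity=1 trackers=5 onsets=5
$ head -8 table.csv
# tactus 0.1.0
# config: context_window=6000.0 concurrence_base=0.01 ...
a,b,onset_index,onset_time,period,phase,score
0,1,1,501.042,500,1.04167,1
0,1,2,1001.04,500,1.04167,1
0,1,3,1501.04,500,1.04167,1
0,1,4,2001.04,500,1.04167,1
0,2,2,1001.04,1000,1.04167,0.666667
```

Tracker (0,1) — the true 500 ms pulse — projects onto every onset and
scores a perfect 1 at each step, so the passage's overall clarity is 1.
Tracker (0,2) is the half-tempo interpretation (δ = 1000 ms): its beats
all land on onsets (precision 1) but it designates only 2 of 3, 2 of 4,
then 3 of 5 onsets as beats, giving the score sequence 0.666667, 0.5,
0.6.

Beat extraction on a passage whose pulse doubles in speed halfway
(500 ms → 250 ms) illustrates the tapping-adapted procedure: the
emitted inter-beat interval stays at 500 ms (the 250 ms pulse is
doubled above the 375 ms tapping floor):

```sh
$ tactus generate period_change -o pc.txt
$ tactus beats pc.txt -o beats.txt --adapted
wrote 23 beats to beats.txt
$ tail -3 beats.txt
10.500
11.000
11.500
```

The same pipeline is available as a library: `tactus.track()` returns a
`TrackingResult` from which `clarity_curve`, `overall_clarity`,
`to_table`, `extract_beats_naive` and `extract_beats_adapted` derive
all artifacts.

## File formats

Onset, tap and beat files are plain text with one time per line
(`#` comments ignored), milliseconds by default or seconds via flag;
beat files default to seconds with 3 decimals for compatibility with
standard beat-evaluation tooling. Tables and clarity curves are CSV
with a `#` header echoing the effective configuration.
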