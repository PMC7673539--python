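"""Projection, matching and the congruency score, checked against a
brute-force oracle that enumerates beat indices and onsets directly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tactus import (
    ModelConfig,
    OnsetSequence,
    TactusHypothesis,
    ValidationError,
    concurrence,
    congruency,
    match,
    project,
)


def brute_congruency(hyp, times, now, config):
    """Independent recomputation: scan all integer beat indices and all
    onsets with plain loops, no searchsorted, no shared helpers."""
    lo = max(times[0], now - config.context_window)
    tol = config.projection_tol
    scope = [r for r in times if lo - tol <= r <= now + tol]
    beats = []
    k = -10000
    while hyp.phase + k * hyp.period <= now + tol:
        b = hyp.phase + k * hyp.period
        if b >= lo - tol:
            beats.append(b)
        k += 1
    if not beats:
        return 0.0
    hits = 0.0
    for b in beats:
        best = min(scope, key=lambda r: (abs(b - r), r))
        hits += config.concurrence_base ** (abs(b - best) / hyp.period)
    score = (hits / len(beats)) * (hits / len(scope))
    return min(max(score, 0.0), 1.0)


class TestProject:
    def test_forward_projection(self):
        p = project(TactusHypothesis(0, 500), 0, 2000)
        assert np.array_equal(p.beat_times, [0, 500, 1000, 1500, 2000])
        assert np.array_equal(np.diff(p.indices), np.ones(4))

    def test_backward_extension_before_phase(self):
        p = project(TactusHypothesis(1000, 400), 0, 2000)
        assert np.array_equal(p.beat_times, [200, 600, 1000, 1400, 1800])
        assert p.indices[0] == -2

    def test_inclusive_bounds_with_tolerance(self):
        # the final beat coincides with the passage end under floating point
        p = project(TactusHypothesis(1.04167, 1000), 1.04167, 2001.04167, 1e-6)
        assert len(p) == 3

    @settings(derandomize=True, max_examples=100)
    @given(phase=st.floats(-1000, 1000), period=st.floats(50, 2000),
           lower=st.floats(0, 5000), width=st.floats(0, 10000))
    def test_matches_brute_force_k_scan(self, phase, period, lower, width):
        upper = lower + width
        got = project(TactusHypothesis(phase, period), lower, upper, 1e-6).beat_times
        ks = np.arange(-300, 300)
        beats = phase + ks * period
        expect = beats[(beats >= lower - 1e-6) & (beats <= upper + 1e-6)]
        assert np.allclose(got, expect)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            project(TactusHypothesis(0, 500), 100, 50)


class TestConcurrence:
    @pytest.mark.parametrize("dist, expect", [
        (0.0, 1.0), (500.0, 0.01), (250.0, 0.1),
    ])
    def test_known_weights(self, dist, expect):
        assert concurrence(1000.0, 1000.0 + dist, 500.0) == pytest.approx(expect)

    def test_symmetric_and_decreasing(self):
        assert concurrence(0, 80, 500) == concurrence(80, 0, 500)
        d = np.linspace(0, 1000, 50)
        w = concurrence(d, 0.0, 500.0)
        assert np.all(np.diff(w) < 0)


class TestMatch:
    def test_exact_match(self):
        p = project(TactusHypothesis(0, 500), 0, 500)
        ms = match(p, OnsetSequence([0, 500]))
        assert np.all(ms.distances == 0)
        assert ms.predictions == 2 and ms.music_events == 2

    def test_tie_breaks_to_earlier_onset(self):
        p = project(TactusHypothesis(0, 500), 0, 1000)
        ms = match(p, OnsetSequence([0, 1000]))
        assert ms.matched_onsets[1] == 0  # beat 500 equidistant; earlier wins

    def test_nearest_neighbor(self):
        p = project(TactusHypothesis(1000, 500), 1000, 1000)
        ms = match(p, OnsetSequence([0, 900, 1500]))
        assert ms.matched_onsets[0] == 900 and ms.distances[0] == 100

    def test_empty_scope_rejected(self):
        p = project(TactusHypothesis(0, 500), 0, 500)
        with pytest.raises(ValidationError):
            match(p, np.array([]))


class TestCongruency:
    @pytest.mark.parametrize("n_onsets, expect", [
        (3, 2 / 3), (4, 1 / 2), (5, 3 / 5),
    ])
    def test_double_period_hypothesis_worked_values(self, worked_example_onsets,
                                                    config, n_onsets, expect):
        """The 1000 ms-period hypothesis on the 500 ms passage misses every
        other onset: precision stays 1 but sensitivity is the fraction of
        onsets hit."""
        hyp = TactusHypothesis(1.04167, 1000.0)
        times = worked_example_onsets.prefix(n_onsets)
        got = congruency(hyp, times, now=times[n_onsets - 1], config=config)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_true_period_hypothesis_scores_one(self, worked_example_onsets, config):
        hyp = TactusHypothesis(1.04167, 500.0)
        for n in (2, 3, 4, 5):
            times = worked_example_onsets.prefix(n)
            assert congruency(hyp, times, times[n - 1], config) == pytest.approx(1.0)

    def test_translation_invariance(self, config):
        times = np.array([0.0, 480.0, 1010.0, 1490.0])
        hyp = TactusHypothesis(0.0, 500.0)
        base = congruency(hyp, times, 1490.0, config)
        shift = 12345.6
        moved = congruency(TactusHypothesis(shift, 500.0), times + shift,
                           1490.0 + shift, config)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_no_projected_beats_scores_zero(self, config):
        # period far longer than the passage, phase beyond its end
        hyp = TactusHypothesis(10000.0, 1300.0)
        assert congruency(hyp, [0.0, 500.0], 500.0, config) == 0.0

    @settings(derandomize=True, max_examples=250, deadline=None)
    @given(st.data())
    def test_equals_brute_force_oracle(self, data):
        config = ModelConfig()
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n = data.draw(st.integers(2, 12))
        times = np.sort(rng.uniform(0, 8000, n))
        if np.min(np.diff(times)) < 1:
            times = np.cumsum(np.maximum(np.diff(np.concatenate([[0], times])), 1))
        hyp = TactusHypothesis(phase=float(rng.uniform(0, 2000)),
                               period=float(rng.uniform(187, 1500)))
        now = float(times[-1])
        got = congruency(hyp, times, now, config)
        expect = brute_congruency(hyp, times, now, config)
        assert got == pytest.approx(expect, rel=1e-9, abs=1e-12)
        assert 0.0 <= got <= 1.0
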