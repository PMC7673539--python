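"""The causal main loop: spawn, correct, score, collapse.

Onsets are processed strictly in order. At each new onset the loop
(1) spawns a tracker for every admissible (earlier onset, current onset)
pair, (2) refits every live tracker's phase and period against the
context window, (3) scores every tracker's congruency and records a
state, and (4) collapses near-duplicate trackers, keeping the oldest.
Nothing after the current onset is ever consulted, so truncating the
input reproduces a prefix of the same histories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .core import (
    ModelConfig,
    NoTrackablePulseError,
    OnsetSequence,
    TactusHypothesis,
    TrackerState,
    ValidationError,
    as_times,
)
from .correction import correct
from .scoring import congruency

__all__ = [
    "HypothesisTracker",
    "TrackingResult",
    "generate_hypotheses",
    "is_similar",
    "track",
    "top_hypothesis_timeline",
]

logger = logging.getLogger("tactus")


@dataclass
class HypothesisTracker:
    """One agent: a tactus hypothesis plus its full tracked evolution.

    Identified by the indices ``(origin_a, origin_b)`` of the onset pair
    that generated it. ``phase``/``period`` are the current (latest
    corrected) parameters; ``history`` holds one state per onset
    processed since creation.
    """

    origin_a: int
    origin_b: int
    phase: float
    period: float
    history: list[TrackerState] = field(default_factory=list)

    @property
    def identity(self) -> tuple[int, int]:
        return (self.origin_a, self.origin_b)

    @property
    def hypothesis(self) -> TactusHypothesis:
        return TactusHypothesis(self.phase, self.period)

    def state_at(self, onset_index: int) -> TrackerState | None:
        """The recorded state at ``onset_index``, or None if not yet created."""
        pos = onset_index - self.origin_b
        if pos < 0 or pos >= len(self.history):
            return None
        return self.history[pos]


@dataclass
class TrackingResult:
    """Everything a causal pass produced: input, config, surviving trackers."""

    onsets: OnsetSequence
    trackers: list[HypothesisTracker]
    config: ModelConfig

    @property
    def n_onsets(self) -> int:
        return len(self.onsets)


def generate_hypotheses(onsets: Union[OnsetSequence, Sequence[float], np.ndarray],
                        t: int, config: ModelConfig | None = None
                        ) -> list[tuple[int, int, TactusHypothesis]]:
    """Candidate hypotheses anchored at onset ``t``.

    Every earlier onset ``a`` defines a candidate with phase ``r_a`` and
    period ``r_t - r_a``, kept only when the period lies within the
    plausible tactus range (187–1500 ms by default, 320 down to 40 bpm).
    """
    config = config or ModelConfig()
    times = as_times(onsets)
    if t < 1 or t >= times.size:
        raise ValidationError(f"onset index {t} out of range for spawning")
    out = []
    for a in range(t):
        period = times[t] - times[a]
        if config.min_period <= period <= config.max_period:
            out.append((a, t, TactusHypothesis(phase=float(times[a]),
                                               period=float(period))))
    return out


def is_similar(h1: TactusHypothesis, h2: TactusHypothesis,
               config: ModelConfig | None = None) -> bool:
    """Whether two hypotheses track the same beat.

    True when the periods agree within ``similarity_rel_period`` of the
    mean period and the phases agree modulo the mean period (circular
    distance) within ``similarity_rel_phase`` of it.
    """
    config = config or ModelConfig()
    mean_period = 0.5 * (h1.period + h2.period)
    if abs(h1.period - h2.period) / mean_period > config.similarity_rel_period:
        return False
    phi1 = h1.phase % mean_period
    phi2 = h2.phase % mean_period
    d = abs(phi1 - phi2)
    d = min(d, mean_period - d)
    return d <= config.similarity_rel_phase * mean_period


def _collapse(trackers: list[HypothesisTracker],
              config: ModelConfig) -> list[HypothesisTracker]:
    # trackers arrive in creation order (origin_b, then origin_a), so a
    # linear scan keeping first occurrences preserves the oldest of each
    # similarity class.
    survivors: list[HypothesisTracker] = []
    for tr in trackers:
        if not any(is_similar(tr.hypothesis, s.hypothesis, config)
                   for s in survivors):
            survivors.append(tr)
    return survivors


def track(onsets: Union[OnsetSequence, Sequence[float], np.ndarray],
          config: ModelConfig | None = None) -> TrackingResult:
    """Run the causal tracking loop over a passage.

    Raises :class:`ValidationError` on fewer than two onsets and
    :class:`NoTrackablePulseError` when no inter-onset interval ever
    falls inside the hypothesis period bounds.
    """
    config = config or ModelConfig()
    seq = onsets if isinstance(onsets, OnsetSequence) else OnsetSequence(as_times(onsets))
    times = seq.times
    n = times.size
    if n < 2:
        raise ValidationError("tracking requires at least 2 onsets")

    trackers: list[HypothesisTracker] = []
    any_created = False
    for t in range(1, n):
        now = float(times[t])
        past = times[: t + 1]
        spawned = generate_hypotheses(past, t, config)
        any_created = any_created or bool(spawned)
        for a, b, h in spawned:
            trackers.append(HypothesisTracker(a, b, h.phase, h.period))
        for tr in trackers:
            corrected, _ = correct(tr.hypothesis, past, now, config)
            tr.phase, tr.period = corrected.phase, corrected.period
            score = congruency(corrected, past, now, config)
            tr.history.append(TrackerState(onset_index=t, onset_time=now,
                                           phase=tr.phase, period=tr.period,
                                           score=score))
        before = len(trackers)
        trackers = _collapse(trackers, config)
        if config.max_trackers is not None and len(trackers) > config.max_trackers:
            ranked = sorted(trackers, key=lambda tr: -tr.history[-1].score)
            keep = set(id(tr) for tr in ranked[: config.max_trackers])
            trackers = [tr for tr in trackers if id(tr) in keep]
            logger.info("step %d: pruned to %d trackers by score", t, len(trackers))
        logger.debug("step %d (t=%.1f ms): spawned %d, collapsed %d, live %d",
                     t, now, len(spawned), before - len(trackers), len(trackers))

    if not any_created:
        raise NoTrackablePulseError(
            "no hypothesis could be created: all inter-onset intervals fall "
            f"outside [{config.min_period}, {config.max_period}] ms"
        )
    return TrackingResult(onsets=seq, trackers=trackers, config=config)


def top_hypothesis_timeline(result: TrackingResult
                            ) -> list[tuple[int, tuple[int, int], float]]:
    """Per processed onset, the best-scoring surviving tracker.

    Returns ``(onset_index, tracker identity, score)`` triples, one per
    onset index >= 1. Ties go to the older tracker (the trackers list is
    kept in creation order).
    """
    out = []
    for t in range(1, result.n_onsets):
        best = None
        best_state = None
        for tr in result.trackers:
            st = tr.state_at(t)
            if st is None:
                continue
            if best_state is None or st.score > best_state.score:
                best, best_state = tr, st
        if best is not None:
            out.append((t, best.identity, best_state.score))
    return out
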