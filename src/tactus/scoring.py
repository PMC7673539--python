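"""Hypothesis projection, beat/onset matching and the congruency score.

The congruency score of a tactus hypothesis against a passage is the
product of a precision term and a sensitivity term::

    score = (hits / predictions) * (hits / music_events)

where ``predictions`` is the number of projected beats in the context
window, ``music_events`` the number of onsets in it, and ``hits`` the
sum over projected beats of a distance weight that equals 1 for an
exact coincidence and decays exponentially with the beat-to-onset
distance measured in periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .core import (
    ModelConfig,
    OnsetSequence,
    Projection,
    TactusHypothesis,
    ValidationError,
    as_times,
)

__all__ = ["MatchSet", "project", "concurrence", "match", "congruency",
           "scoring_window"]


@dataclass(frozen=True)
class MatchSet:
    """Each projected beat paired with its nearest onset.

    ``predictions`` counts projected beats, ``music_events`` counts
    onsets in the matching scope; both enter the congruency ratio.
    """

    beat_times: np.ndarray
    matched_onsets: np.ndarray
    distances: np.ndarray
    predictions: int
    music_events: int


def project(hypothesis: TactusHypothesis, lower: float, upper: float,
            tol: float = 1e-6) -> Projection:
    """Beat times ``phase + k * period`` (k integer) within ``[lower, upper]``.

    Bounds are inclusive with absolute tolerance ``tol``; negative k
    (beats before the phase) are included, so the projection extends
    backwards to the start of the window.
    """
    if not hypothesis.period > 0:
        raise ValidationError("cannot project a non-positive period")
    if lower > upper:
        raise ValidationError(f"empty projection interval [{lower}, {upper}]")
    rho, delta = hypothesis.phase, hypothesis.period
    k_lo = math.ceil((lower - tol - rho) / delta)
    k_hi = math.floor((upper + tol - rho) / delta)
    ks = np.arange(k_lo, k_hi + 1, dtype=int)
    return Projection(indices=ks, beat_times=rho + ks * delta)


def concurrence(p: Union[float, np.ndarray], r: Union[float, np.ndarray],
                period: float, base: float = 0.01) -> Union[float, np.ndarray]:
    """Distance weight of a projected beat against its matched onset.

    ``base ** (|p - r| / period)``: 1 at zero distance, ``base`` at one
    full period, symmetric in its two time arguments.
    """
    if not period > 0:
        raise ValidationError("period must be > 0")
    return base ** (np.abs(np.asarray(p, dtype=float) - r) / period)


def match(projection: Projection,
          onsets: Union[OnsetSequence, Sequence[float], np.ndarray]) -> MatchSet:
    """Pair every projected beat with the nearest onset in scope.

    Ties (a beat equidistant from two onsets) resolve toward the
    earlier onset. The scope is whatever onset array the caller passes;
    the tracking loop passes the onsets inside the context window.
    """
    times = as_times(onsets)
    if times.size == 0:
        raise ValidationError("cannot match against an empty onset scope")
    beats = projection.beat_times
    right = np.searchsorted(times, beats)
    left = np.clip(right - 1, 0, times.size - 1)
    right = np.clip(right, 0, times.size - 1)
    d_left = np.abs(beats - times[left])
    d_right = np.abs(beats - times[right])
    # tie (d_left == d_right) picks the earlier (left) onset
    take_left = d_left <= d_right
    matched = np.where(take_left, times[left], times[right])
    return MatchSet(
        beat_times=beats,
        matched_onsets=matched,
        distances=np.abs(beats - matched),
        predictions=int(beats.size),
        music_events=int(times.size),
    )


def scoring_window(onset_times: np.ndarray, now: float,
                   config: ModelConfig) -> tuple[float, float]:
    """Context window ``[max(first onset, now - context_window), now]``.

    The window never extends before the passage start, so projections
    stay within the heard passage in both directions.
    """
    return max(float(onset_times[0]), now - config.context_window), now


def congruency(hypothesis: TactusHypothesis,
               onsets: Union[OnsetSequence, Sequence[float], np.ndarray],
               now: float, config: ModelConfig | None = None) -> float:
    """Congruency score of a hypothesis at time ``now``, in [0, 1].

    Projected beats, hits and onset counts are all taken inside the
    context window ending at ``now``. A hypothesis with no projected
    beat in the window scores 0 (it makes no prediction there). The
    product of the two ratios is clamped to [0, 1]: several beats may
    share one nearest onset, which can push the sensitivity ratio
    marginally above 1.
    """
    config = config or ModelConfig()
    times = as_times(onsets)
    if times.size == 0:
        raise ValidationError("cannot score against an empty passage")
    lo, hi = scoring_window(times, now, config)
    tol = config.projection_tol
    scope = times[(times >= lo - tol) & (times <= hi + tol)]
    if scope.size == 0:
        raise ValidationError("no onsets inside the scoring window")
    proj = project(hypothesis, lo, hi, tol)
    if len(proj) == 0:
        return 0.0
    ms = match(proj, scope)
    hits = float(np.sum(concurrence(ms.beat_times, ms.matched_onsets,
                                    hypothesis.period, config.concurrence_base)))
    score = (hits / ms.predictions) * (hits / ms.music_events)
    return min(max(score, 0.0), 1.0)
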