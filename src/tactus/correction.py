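"""Phase/period correction against expressive timing.

Real performances are not metronomic: onsets drift around the nominal
beat grid. Each tracker therefore refits its hypothesis at every onset
by an ordinary least-squares line through the *corrected prediction
error* of its windowed beat projection:

    ce_k = m * (r_k - p_k) * d ** (|p_k - r_k| / period)

where ``p_k`` is a projected beat, ``r_k`` its nearest onset, ``m`` the
multiplier and ``d`` the decay. The attenuation term sends the error of
beats with no nearby onset back to zero so they barely influence the
fit. Regressing ce_k on the integer beat index k makes the fitted slope
a period correction (ms per beat) and the intercept a phase correction
(ms), which are added to the hypothesis parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .core import ModelConfig, OnsetSequence, TactusHypothesis, as_times
from .scoring import match, project, scoring_window

__all__ = ["Correction", "corrected_error", "correct"]

logger = logging.getLogger("tactus")


@dataclass(frozen=True)
class Correction:
    """A fitted correction: phase shift (ms) and period shift (ms/beat)."""

    delta_phase: float
    delta_period: float
    n_points: int

    @property
    def is_zero(self) -> bool:
        return self.delta_phase == 0.0 and self.delta_period == 0.0


def corrected_error(p: Union[float, np.ndarray], r: Union[float, np.ndarray],
                    period: float, m: float = 2.0,
                    d: float = 1e-4) -> Union[float, np.ndarray]:
    """Signed, distance-attenuated projection error ``m (r-p) d^(|p-r|/period)``.

    Zero iff the beat and onset coincide; odd in ``r - p``; decays to
    zero as the distance grows, so unmatched beats contribute nothing.
    """
    if not period > 0:
        raise ValueError("period must be > 0")
    p = np.asarray(p, dtype=float)
    return m * (r - p) * d ** (np.abs(p - r) / period)


def correct(hypothesis: TactusHypothesis,
            onsets: Union[OnsetSequence, Sequence[float], np.ndarray],
            now: float,
            config: ModelConfig | None = None) -> tuple[TactusHypothesis, Correction]:
    """Refit a hypothesis against the onsets in the context window at ``now``.

    Returns the corrected hypothesis and the applied correction. With
    fewer than two projected beats in the window no line can be fitted
    and the correction is zero. A corrected period that would be
    non-positive (degenerate input) is clamped to the smallest positive
    float and logged.
    """
    config = config or ModelConfig()
    times = as_times(onsets)
    zero = Correction(0.0, 0.0, 0)
    if times.size == 0:
        return hypothesis, zero
    lo, hi = scoring_window(times, now, config)
    tol = config.projection_tol
    scope = times[(times >= lo - tol) & (times <= hi + tol)]
    if scope.size == 0:
        return hypothesis, zero
    proj = project(hypothesis, lo, hi, tol)
    if len(proj) < 2:
        return hypothesis, zero
    ms = match(proj, scope)
    ce = corrected_error(ms.beat_times, ms.matched_onsets, hypothesis.period,
                         config.corr_multiplier, config.corr_decay)
    slope, intercept = np.polyfit(proj.indices.astype(float), ce, 1)
    corr = Correction(float(intercept), float(slope), int(len(proj)))
    new_period = hypothesis.period + corr.delta_period
    if new_period <= 0:
        logger.warning(
            "correction drove period non-positive (%.6g); clamping", new_period
        )
        new_period = float(np.finfo(float).tiny)
    corrected = TactusHypothesis(phase=hypothesis.phase + corr.delta_phase,
                                 period=new_period)
    return corrected, corr
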