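"""Derived artifacts: state table, clarity curve, overall clarity, beat tracks.

The tracking pass keeps every surviving agent's full evolution; this
module flattens that into the human-facing outputs: a tabular dump of
all tracker states, the pulse-clarity curve (top score over time), its
mean (overall clarity), and designated beat times extracted either
naively (project whichever hypothesis currently scores best) or with
the tapping-oriented adaptations (slow-tempo doubling and adoption
hysteresis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import MS_PER_SECOND, ModelConfig, TactusHypothesis, ValidationError
from .scoring import project
from .tracking import HypothesisTracker, TrackingResult, top_hypothesis_timeline

__all__ = [
    "ClarityCurve",
    "adapted_incumbent_timeline",
    "BeatTrack",
    "to_table",
    "write_table",
    "clarity_curve",
    "write_clarity_curve",
    "overall_clarity",
    "extract_beats_naive",
    "extract_beats_adapted",
]

TABLE_COLUMNS = ["a", "b", "onset_index", "onset_time", "period", "phase", "score"]

#: merge distance (ms) for coincident beats at segment seams
BEAT_MERGE_EPS = 10.0


@dataclass(frozen=True)
class ClarityCurve:
    """Top congruency score over time: one point per processed onset."""

    times: np.ndarray
    scores: np.ndarray
    trackers: list[tuple[int, int]]

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BeatTrack:
    """Designated beat times (ms), strictly increasing."""

    beat_times: np.ndarray

    def __len__(self) -> int:
        return self.beat_times.size

    def inter_beat_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


def to_table(result: TrackingResult) -> pd.DataFrame:
    """All tracker states as one DataFrame, one row per state.

    Rows are grouped by tracker and ordered by (a, b, onset_index);
    values are unrounded floats (see :func:`write_table` for display
    formatting).
    """
    rows = []
    for tr in sorted(result.trackers, key=lambda tr: tr.identity):
        for st in tr.history:
            rows.append((tr.origin_a, tr.origin_b, st.onset_index, st.onset_time,
                         st.period, st.phase, st.score))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def format_sig(value: float, digits: int = 6) -> str:
    """Format to ``digits`` significant figures, integers printed bare."""
    return f"{value:.{digits}g}"


def write_table(df: pd.DataFrame, path: Union[str, Path],
                header_comments: tuple[str, ...] = ()) -> None:
    """Write the state table as CSV with 6-significant-digit numbers."""
    out = df.copy()
    for col in ("onset_time", "period", "phase", "score"):
        out[col] = out[col].map(format_sig)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def clarity_curve(result: TrackingResult) -> ClarityCurve:
    """The congruency score of the best hypothesis at each processed onset."""
    timeline = top_hypothesis_timeline(result)
    times = np.array([result.onsets.times[t] for t, _, _ in timeline])
    scores = np.array([s for _, _, s in timeline])
    return ClarityCurve(times=times, scores=scores,
                        trackers=[ident for _, ident, _ in timeline])


def write_clarity_curve(curve: ClarityCurve, path: Union[str, Path],
                        header_comments: tuple[str, ...] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("onset_time,score,tracker\n")
        for t, s, ident in zip(curve.times, curve.scores, curve.trackers):
            fh.write(f"{format_sig(t)},{format_sig(s)},{ident[0]}-{ident[1]}\n")


def overall_clarity(result: TrackingResult) -> float:
    """Mean of the top congruency score over all updates — the passage's
    overall pulse clarity, in [0, 1]."""
    curve = clarity_curve(result)
    if len(curve) == 0:
        raise ValidationError("no clarity points: passage produced no tracked state")
    return float(np.mean(curve.scores))


def _dedup(beats: list[float], min_gap: float) -> np.ndarray:
    out: list[float] = []
    for b in beats:
        if not out or b - out[-1] >= min_gap:
            out.append(b)
    return np.asarray(out)


def _tracker_by_identity(result: TrackingResult,
                         ident: tuple[int, int]) -> HypothesisTracker:
    for tr in result.trackers:
        if tr.identity == ident:
            return tr
    raise KeyError(ident)


def extract_beats_naive(result: TrackingResult) -> BeatTrack:
    """Beat track from forward projection of the current top hypothesis.

    Walking the onsets in order, each half-open segment
    ``[r_t, r_{t+1})`` is owned by the hypothesis that scored best once
    ``r_t`` was processed (post-update parameters); its projected beats
    within the segment are emitted. The final segment is closed at the
    last onset time. Beats are never snapped to onsets — emission is
    purely predictive. Because beats typically fall exactly on onsets,
    ownership boundaries are drawn a merge-epsilon (10 ms) *before*
    each onset so sub-millisecond parameter wobble cannot drop a seam
    beat; duplicates closer than the same epsilon are merged, keeping
    the earlier beat.
    """
    timeline = top_hypothesis_timeline(result)
    times = result.onsets.times
    tol = result.config.projection_tol
    eps = BEAT_MERGE_EPS
    beats: list[float] = []
    for t, ident, _ in timeline:
        tr = _tracker_by_identity(result, ident)
        st = tr.state_at(t)
        final = t == len(times) - 1
        seg_lo = float(times[t]) - eps
        seg_hi = float(times[t]) if final else float(times[t + 1]) - eps
        proj = project(TactusHypothesis(st.phase, st.period), seg_lo, seg_hi, tol)
        for b in proj.beat_times:
            if final or b < seg_hi - tol:
                beats.append(float(b))
    return BeatTrack(beat_times=_dedup(beats, eps))


def _n_doublings(period: float, min_tap_period: float) -> int:
    n = 0
    while period * (2 ** n) <= min_tap_period:
        n += 1
    return n


def _choose_offset(state, n_doub: int, recent_beats: list[float]) -> int:
    """Pick the phase offset multiple j so the doubled grid stays closest
    to the beats already emitted (continuity across adoptions)."""
    if n_doub == 0 or not recent_beats:
        return 0
    big = state.period * (2 ** n_doub)
    best_j, best_cost = 0, None
    for j in range(2 ** n_doub):
        phase = state.phase + j * state.period
        cost = 0.0
        for b in recent_beats:
            d = (b - phase) % big
            cost += min(d, big - d)
        cost /= len(recent_beats)
        if best_cost is None or cost < best_cost:
            best_j, best_cost = j, cost
    return best_j


def adapted_incumbent_timeline(result: TrackingResult,
                               adoption_lag: float = 3000.0
                               ) -> list[tuple[int, tuple[int, int]]]:
    """Which tracker generates beats at each onset, under adoption hysteresis.

    The first top-scoring tracker becomes the incumbent. A challenger
    replaces it only after strictly outscoring it at every update for
    more than ``adoption_lag`` ms of onset time; any lapse (or a change
    of challenger) restarts the clock. Returns one
    ``(onset_index, tracker identity)`` pair per processed onset.
    """
    timeline = top_hypothesis_timeline(result)
    times = result.onsets.times
    out: list[tuple[int, tuple[int, int]]] = []
    incumbent_ident: tuple[int, int] | None = None
    challenger_ident: tuple[int, int] | None = None
    challenge_since = 0.0
    for t, best_ident, best_score in timeline:
        now = float(times[t])
        if incumbent_ident is None:
            incumbent_ident = best_ident
        inc_state = _tracker_by_identity(result, incumbent_ident).state_at(t)
        if inc_state is None:
            # incumbent not yet created at this index (possible only in
            # pathological configs); adopt the current best outright
            incumbent_ident = best_ident
            challenger_ident = None
        elif best_ident != incumbent_ident and best_score > inc_state.score:
            if challenger_ident != best_ident:
                challenger_ident = best_ident
                challenge_since = now
            elif now - challenge_since > adoption_lag:
                incumbent_ident = best_ident
                challenger_ident = None
        else:
            challenger_ident = None
        out.append((t, incumbent_ident))
    return out


def extract_beats_adapted(result: TrackingResult, min_tap_period: float = 375.0,
                          adoption_lag: float = 3000.0) -> BeatTrack:
    """Beat track adapted toward plausible tapping behavior.

    Two changes relative to :func:`extract_beats_naive`:

    - **Tempo floor.** The working period is doubled, as many times as
      needed, until it exceeds ``min_tap_period`` (default 375 ms, i.e.
      no faster than 160 bpm), since listeners do not sustain tapping
      above that rate. When doubling, the emitted phase is chosen among
      the offsets ``phase + j * period`` of the undoubled grid to
      minimize the mean distance to the beats already emitted.
    - **Adoption hysteresis.** A challenger hypothesis replaces the
      incumbent only after outscoring it continuously for more than
      ``adoption_lag`` ms of onset time (default 3000 ms), suppressing
      rapid switching between rival interpretations.

    Beats that would land within ``min_tap_period`` of the previously
    emitted beat (possible at adoption seams) are dropped, so the output
    inter-beat interval always exceeds the tempo floor.
    """
    timeline = top_hypothesis_timeline(result)
    if not timeline:
        return BeatTrack(beat_times=np.array([]))
    times = result.onsets.times
    tol = result.config.projection_tol

    incumbents = dict(adapted_incumbent_timeline(result, adoption_lag))
    incumbent_ident = None
    incumbent_j = 0
    beats: list[float] = []

    for t, _best_ident, _best_score in timeline:
        now = float(times[t])
        adopted = incumbents[t] != incumbent_ident
        incumbent_ident = incumbents[t]
        incumbent = _tracker_by_identity(result, incumbent_ident)
        inc_state = incumbent.state_at(t)
        if adopted:
            nd = _n_doublings(inc_state.period, min_tap_period)
            incumbent_j = _choose_offset(inc_state, nd, beats[-4:])

        nd = _n_doublings(inc_state.period, min_tap_period)
        work_period = inc_state.period * (2 ** nd)
        work_phase = inc_state.phase + min(incumbent_j, 2 ** nd - 1) * inc_state.period
        final = t == len(times) - 1
        seg_lo = now - BEAT_MERGE_EPS
        seg_hi = now if final else float(times[t + 1]) - BEAT_MERGE_EPS
        proj = project(TactusHypothesis(work_phase, work_period), seg_lo, seg_hi, tol)
        for b in proj.beat_times:
            if final or b < seg_hi - tol:
                if not beats or b - beats[-1] > min_tap_period:
                    beats.append(float(b))
    return BeatTrack(beat_times=np.asarray(beats))
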