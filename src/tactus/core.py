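"""Domain types, model configuration and onset-list I/O.

All times inside the package are milliseconds stored as floats; unit
conversion happens only when reading or writing files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

MS_PER_SECOND = 1000.0

__all__ = [
    "ParseError",
    "ValidationError",
    "NoTrackablePulseError",
    "OnsetSequence",
    "TactusHypothesis",
    "Projection",
    "TrackerState",
    "ModelConfig",
    "read_onsets",
    "write_times",
]


class ValidationError(ValueError):
    """A value violates a model invariant (e.g. non-increasing onsets)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class NoTrackablePulseError(RuntimeError):
    """No tactus hypothesis could ever be created from the input.

    Raised when every inter-onset interval in the passage falls outside
    the allowed hypothesis-period range.
    """


def as_times(onsets: Union["OnsetSequence", Sequence[float], np.ndarray]) -> np.ndarray:
    """Coerce an onset container to a float ndarray of times in ms."""
    if isinstance(onsets, OnsetSequence):
        return onsets.times
    return np.asarray(onsets, dtype=float)


class OnsetSequence:
    """A strictly increasing sequence of event times in milliseconds.

    This is the model's only input observable: the start times of the
    rhythmic events of a passage. Monotonicity is enforced on
    construction; duplicate times are rejected (merging coincident
    events is a preprocessing concern, not the tracker's).

    Parameters
    ----------
    times
        Event times in ms, strictly increasing, finite and >= 0.
    """

    __slots__ = ("_times",)

    def __init__(self, times: Iterable[float]):
        arr = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                         dtype=float)
        if arr.ndim != 1:
            raise ValidationError("onset times must be one-dimensional")
        if arr.size and not np.all(np.isfinite(arr)):
            pos = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValidationError(f"non-finite onset time at position {pos}")
        if arr.size and arr[0] < 0:
            raise ValidationError("onset times must be >= 0 (position 0)")
        if arr.size > 1:
            diffs = np.diff(arr)
            bad = np.flatnonzero(diffs <= 0)
            if bad.size:
                pos = int(bad[0]) + 1
                raise ValidationError(
                    f"onset times must be strictly increasing: violation at position {pos} "
                    f"({arr[pos]} after {arr[pos - 1]})"
                )
        self._times = arr
        self._times.setflags(write=False)

    @property
    def times(self) -> np.ndarray:
        return self._times

    def __len__(self) -> int:
        return self._times.size

    def __iter__(self) -> Iterator[float]:
        return iter(self._times)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return OnsetSequence(self._times[idx])
        return float(self._times[idx])

    def prefix(self, n: int) -> "OnsetSequence":
        """The first ``n`` onsets (used for causal truncation)."""
        return OnsetSequence(self._times[:n])

    def __eq__(self, other) -> bool:
        if isinstance(other, OnsetSequence):
            return np.array_equal(self._times, other._times)
        return NotImplemented

    def __repr__(self) -> str:
        return f"OnsetSequence(n={len(self)}, span=[{self._times[0] if len(self) else None}, {self._times[-1] if len(self) else None}])"


@dataclass(frozen=True)
class TactusHypothesis:
    """An isochronous pulse candidate: first beat time and beat period.

    Attributes
    ----------
    phase
        Time of the reference beat (ms); beats lie at ``phase + k * period``.
    period
        Inter-beat interval (ms), strictly positive.
    """

    phase: float
    period: float

    def __post_init__(self):
        if not self.period > 0:
            raise ValidationError(f"hypothesis period must be > 0, got {self.period}")


@dataclass(frozen=True)
class Projection:
    """Beat times of a hypothesis restricted to a time window.

    ``beat_times[i] == phase + indices[i] * period``; indices are
    consecutive integers (negative indices extend backwards from the
    phase).
    """

    indices: np.ndarray
    beat_times: np.ndarray

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass(frozen=True)
class TrackerState:
    """Snapshot of one tracker after processing one onset.

    Scores live in [0, 1]; phase and period are the post-correction
    parameters at that onset.
    """

    onset_index: int
    onset_time: float
    phase: float
    period: float
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must be in [0, 1], got {self.score}")

    @property
    def hypothesis(self) -> TactusHypothesis:
        return TactusHypothesis(self.phase, self.period)


@dataclass(frozen=True)
class ModelConfig:
    """Model parameters.

    Attributes
    ----------
    context_window
        How much passage context (ms) before the current onset is used
        when scoring and correcting hypotheses. Default 6000 ms.
    concurrence_base
        Base of the exponential distance weight used when counting a
        projected beat as a hit; a beat one full period away from its
        nearest onset contributes this much. Default 0.01.
    corr_multiplier
        Sensitivity of the correction to the signed projection error
        (``m``). Default 2.
    corr_decay
        How quickly a projection error is discounted with distance in
        the correction (``d``); small values ignore far onsets sooner.
        Default 1e-4.
    min_period, max_period
        Allowed period range (ms) for newly generated hypotheses:
        187–1500 ms, i.e. 320 down to 40 beats per minute.
    similarity_rel_period
        Two trackers are considered duplicates when their periods differ
        by at most this fraction of the mean period (and phases agree,
        below). Default 2%.
    similarity_rel_phase
        Maximum circular phase distance, as a fraction of the mean
        period, for two trackers to be considered duplicates. Default 2%.
    projection_tol
        Absolute tolerance (ms) for inclusive window-boundary tests when
        projecting beats.
    max_trackers
        Optional cap on live trackers after each step (pruned by score,
        keeping older trackers on ties). ``None`` (default) disables
        pruning, matching the model's unbounded agent population.
    """

    context_window: float = 6000.0
    concurrence_base: float = 0.01
    corr_multiplier: float = 2.0
    corr_decay: float = 1e-4
    min_period: float = 187.0
    max_period: float = 1500.0
    similarity_rel_period: float = 0.02
    similarity_rel_phase: float = 0.02
    projection_tol: float = 1e-6
    max_trackers: int | None = None

    def __post_init__(self):
        for name in ("context_window", "concurrence_base", "corr_multiplier",
                     "corr_decay", "min_period", "max_period",
                     "similarity_rel_period", "similarity_rel_phase",
                     "projection_tol"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("concurrence_base", "corr_decay"):
            if not getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not self.min_period < self.max_period:
            raise ValidationError("min_period must be < max_period")
        if self.max_trackers is not None and self.max_trackers < 1:
            raise ValidationError("max_trackers must be >= 1 or None")


def _unit_scale(units: str) -> float:
    if units == "ms":
        return 1.0
    if units == "s":
        return MS_PER_SECOND
    raise ValueError(f"unknown units {units!r}: expected 'ms' or 's'")


def read_onsets(path: Union[str, Path], units: str = "ms") -> OnsetSequence:
    """Read an onset/tap/beat file: one time per line, ``#`` comments ignored.

    Parameters
    ----------
    path
        Plain-text file with one numeric time per non-empty line.
    units
        ``"ms"`` (default) or ``"s"``; values are converted to ms.

    Raises
    ------
    ParseError
        On a non-numeric line (carries the 1-based line number).
    ValidationError
        If times are not strictly increasing or fewer than 2 onsets
        are present.
    """
    scale = _unit_scale(units)
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line) * scale)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: not a number: {line!r}", lineno
                ) from None
    if len(values) < 2:
        raise ValidationError(f"{path}: at least 2 onsets required, got {len(values)}")
    return OnsetSequence(values)


def _format_ms(value: float) -> str:
    # Fixed-point with trailing zeros stripped round-trips exactly at
    # microsecond precision and prints integers bare ("500", not "500.0").
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_times(times: Union[OnsetSequence, Sequence[float], np.ndarray],
                path: Union[str, Path], units: str = "ms",
                header: Sequence[str] = ()) -> None:
    """Write times (ms) one per line; seconds output uses 3 decimals.

    ``header`` lines, if given, are written first as ``#`` comments so a
    round trip through :func:`read_onsets` ignores them.
    """
    arr = as_times(times)
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValidationError("times must be increasing")
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for t in arr:
            if units == "s":
                fh.write(f"{t / MS_PER_SECOND:.3f}\n")
            elif units == "ms":
                fh.write(_format_ms(float(t)) + "\n")
            else:
                raise ValueError(f"unknown units {units!r}: expected 'ms' or 's'")
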