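"""Deterministic synthetic rhythm generators.

These produce the onset sequences used to probe the tracker: a plain
isochronous pulse, a passage whose pulse doubles in speed halfway, a
passage whose phase jumps forward and back, a progressive slowdown
(rallentando), a concatenation of mixed rhythmic subpatterns over a
common tactus, and seeded uniform timing jitter for parameter-recovery
experiments. All generators are pure functions of their arguments (and
seed, where applicable) and return validated onset sequences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import OnsetSequence, ValidationError

__all__ = [
    "isochronous",
    "period_change",
    "phase_change",
    "rallentando",
    "mixed_patterns",
    "jitter",
    "DEFAULT_MIXED_SUBPATTERNS",
]

#: five subpatterns over a 500 ms tactus: the plain pulse, two
#: subdivided patterns (incl. the 3-3-2 "tresillo"), a long-short
#: pattern and a syncopated subdivision.
DEFAULT_MIXED_SUBPATTERNS: tuple[tuple[float, ...], ...] = (
    (500.0,),
    (250.0, 250.0, 500.0),
    (375.0, 375.0, 250.0),
    (500.0, 1000.0),
    (250.0, 250.0, 250.0, 750.0),
)


def isochronous(n: int, ioi: float, phase: float = 0.0) -> OnsetSequence:
    """``n`` onsets at ``phase + k * ioi``."""
    if n < 2:
        raise ValidationError("isochronous stimulus needs n >= 2")
    if not ioi > 0:
        raise ValidationError("ioi must be > 0")
    return OnsetSequence(phase + ioi * np.arange(n))


def period_change(n1: int = 12, ioi1: float = 500.0,
                  n2: int = 24, ioi2: float = 250.0) -> OnsetSequence:
    """Isochronous passage whose pulse switches rate partway.

    ``n1`` onsets at ``ioi1``, then ``n2`` more continuing at ``ioi2``
    from the last time. Defaults produce a 500 ms pulse that becomes
    twice as fast in its (longer) second half.
    """
    if n1 < 1 or n2 < 1 or n1 + n2 < 2:
        raise ValidationError("need at least 2 onsets in total")
    if not (ioi1 > 0 and ioi2 > 0):
        raise ValidationError("IOIs must be > 0")
    first = ioi1 * np.arange(n1)
    second = first[-1] + ioi2 * np.arange(1, n2 + 1)
    return OnsetSequence(np.concatenate([first, second]))


def phase_change(n: int = 30, ioi: float = 500.0,
                 shift_points: Sequence[float] = (1 / 3, 2 / 3),
                 shift: float | None = None) -> OnsetSequence:
    """Isochronous grid whose phase jumps at interior change points.

    At each change-point fraction all later onsets shift forward by
    ``shift`` (default half a period). With the default two change
    points the first jump pushes the beat to counter-phase and the
    second restores the original phase class (two half-period shifts
    add up to a whole period), without time ever running backward.
    """
    if n < 2:
        raise ValidationError("phase-change stimulus needs n >= 2")
    if not ioi > 0:
        raise ValidationError("ioi must be > 0")
    if shift is None:
        shift = ioi / 2
    for f in shift_points:
        if not 0 < f < 1:
            raise ValidationError("shift points must be interior fractions")
    times = ioi * np.arange(n, dtype=float)
    for f in sorted(shift_points):
        times[int(np.ceil(f * n)):] += shift
    return OnsetSequence(times)


def rallentando(n: int = 30, ioi0: float = 400.0,
                factor: float = 1.01) -> OnsetSequence:
    """Progressive tempo change: IOI_k = ioi0 * factor**k.

    ``factor > 1`` (default 1.01) slows down — the expressive
    rallentando; ``factor < 1`` accelerates; ``factor = 1`` degenerates
    to an isochronous pulse.
    """
    if n < 2:
        raise ValidationError("rallentando stimulus needs n >= 2")
    if not (ioi0 > 0 and factor > 0):
        raise ValidationError("ioi0 and factor must be > 0")
    iois = ioi0 * factor ** np.arange(n - 1)
    return OnsetSequence(np.concatenate([[0.0], np.cumsum(iois)]))


def mixed_patterns(subpatterns: Sequence[Sequence[float]] = DEFAULT_MIXED_SUBPATTERNS,
                   repeats: int = 4) -> OnsetSequence:
    """Concatenation of rhythmic subpatterns, each repeated in place.

    Each subpattern is a list of IOIs; repeating and chaining them
    yields a passage whose rhythm changes texture while (by default)
    keeping a common 500 ms tactus. Some default subpatterns are not
    isochronous, which lowers the passage's pulse clarity relative to a
    plain pulse.
    """
    if len(subpatterns) < 2:
        raise ValidationError("need at least 2 subpatterns")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    iois: list[float] = []
    for pat in subpatterns:
        if not pat:
            raise ValidationError("empty subpattern")
        if any(not x > 0 for x in pat):
            raise ValidationError("IOIs must be > 0")
        iois.extend(list(pat) * repeats)
    return OnsetSequence(np.concatenate([[0.0], np.cumsum(iois)]))


def jitter(onsets: OnsetSequence, amplitude: float, seed: int) -> OnsetSequence:
    """Independent uniform ±``amplitude`` perturbation of every onset.

    Deterministic given the seed. The amplitude must stay below half the
    smallest IOI so ordering cannot break.
    """
    times = onsets.times
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if amplitude == 0:
        return OnsetSequence(times)
    min_ioi = float(np.min(np.diff(times))) if times.size > 1 else np.inf
    if not amplitude < min_ioi / 2:
        raise ValidationError(
            f"jitter amplitude {amplitude} must be < half the minimum IOI ({min_ioi / 2})"
        )
    rng = np.random.default_rng(seed)
    perturbed = times + rng.uniform(-amplitude, amplitude, size=times.size)
    perturbed[0] = max(perturbed[0], 0.0)  # times must stay non-negative
    return OnsetSequence(perturbed)
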