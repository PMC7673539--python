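"""Tapping-variability statistics.

The empirical proxy for pulse clarity is how steadily listeners tap
along: the coefficient of variability (CV) of each annotator's
inter-tap intervals — standard deviation over mean — computed after
discarding implausibly long intervals (slower than 20 bpm, i.e. above
3000 ms, typically missed taps). Being a ratio, the CV is invariant to
the tapping rate the listener chose and to time translation; lower
values mean steadier tapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .core import OnsetSequence, ValidationError, as_times

__all__ = ["TapRecord", "UndefinedCVError", "intertap_cv", "mean_cv", "cv_report"]

DEFAULT_MAX_ITI = 3000.0


class UndefinedCVError(ValidationError):
    """Fewer than 2 inter-tap intervals survive the filter."""


@dataclass(frozen=True)
class TapRecord:
    """One annotator's tap times (ms, strictly increasing)."""

    annotator: str
    tap_times: OnsetSequence

    @classmethod
    def from_times(cls, annotator: str,
                   times: Union[Sequence[float], np.ndarray]) -> "TapRecord":
        return cls(annotator, OnsetSequence(as_times(times)))


def intertap_cv(taps: Union[TapRecord, OnsetSequence, Sequence[float], np.ndarray],
                max_iti: float = DEFAULT_MAX_ITI, ddof: int = 1) -> float:
    """Coefficient of variability of the inter-tap intervals.

    Intervals strictly greater than ``max_iti`` are discarded first;
    the CV is the sample standard deviation (``ddof=1``; configurable)
    of the surviving intervals divided by their mean.

    Raises :class:`UndefinedCVError` when fewer than 2 intervals
    survive.
    """
    times = taps.tap_times.times if isinstance(taps, TapRecord) else as_times(taps)
    itis = np.diff(times)
    kept = itis[itis <= max_iti]
    if kept.size < 2:
        raise UndefinedCVError(
            f"CV undefined: {kept.size} inter-tap interval(s) survive the "
            f"{max_iti} ms filter"
        )
    return float(np.std(kept, ddof=ddof) / np.mean(kept))


def mean_cv(records: Iterable[TapRecord],
            max_iti: float = DEFAULT_MAX_ITI) -> float:
    """Mean per-annotator CV for one track.

    Annotators whose CV is undefined after filtering are excluded from
    the mean (use :func:`cv_report` to see who was excluded).
    """
    cvs = []
    for rec in records:
        try:
            cvs.append(intertap_cv(rec, max_iti))
        except UndefinedCVError:
            continue
    if not cvs:
        raise UndefinedCVError("no annotator has a defined CV")
    return float(np.mean(cvs))


def cv_report(records: Iterable[TapRecord],
              max_iti: float = DEFAULT_MAX_ITI) -> pd.DataFrame:
    """Per-annotator CV table with an ``excluded`` flag for undefined CVs."""
    rows = []
    for rec in records:
        try:
            rows.append((rec.annotator, intertap_cv(rec, max_iti), False))
        except UndefinedCVError:
            rows.append((rec.annotator, np.nan, True))
    return pd.DataFrame(rows, columns=["annotator", "cv", "excluded"])
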