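"""Epoch selection from continuous emotion-rating traces.

Subjects rate emotional intensity continuously (the reference design uses
a 21-level scale sampled at 10 Hz).  One low- and one high-intensity
epoch are chosen on the group-median trace so that the two windows
(1) are equal in length, (2) differ significantly in ratings by a
Wilcoxon signed-rank test, and (3) are as long as possible — candidate
lengths start at half the trace and shrink until a passing pair exists.
The chosen windows are then mapped onto fMRI volume (TR) indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "RatingTrace",
    "EpochPair",
    "NoSeparableEpochsError",
    "rating_auc",
    "median_trace",
    "find_epoch_pair",
    "epochs_to_tr",
]


class NoSeparableEpochsError(RuntimeError):
    """No equal-length window pair satisfies the Wilcoxon criterion."""


@dataclass
class RatingTrace:
    """A continuous rating trace for one subject.

    ``samples`` live on a discrete scale with ``scale_levels`` degrees
    (values in [0, scale_levels - 1]); ``rate_hz`` is the sampling rate.
    Gaps must be interpolated (or the trace rejected) before construction.
    """

    subject_id: str
    samples: np.ndarray
    rate_hz: float = 10.0
    scale_levels: int = 21

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("rating samples must be a 1-D vector")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError(
                f"{self.subject_id!r}: rating trace has gaps/non-finite samples; "
                "interpolate or reject before analysis"
            )
        lo, hi = 0.0, float(self.scale_levels - 1)
        if self.samples.size and (
            self.samples.min() < lo - 1e-9 or self.samples.max() > hi + 1e-9
        ):
            raise ValueError(
                f"{self.subject_id!r}: samples outside [0, {hi:g}] rating scale"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


@dataclass
class EpochPair:
    """One low- and one high-intensity window, equal length, in seconds.

    Windows are half-open ``[start_s, end_s)``; ``tr_windows`` (filled by
    :func:`epochs_to_tr`) are the matching half-open TR-index intervals.
    """

    low_window: Tuple[float, float]
    high_window: Tuple[float, float]
    wilcoxon_p: float
    median_diff: float = float("nan")
    tr_windows: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        ll = self.low_window[1] - self.low_window[0]
        lh = self.high_window[1] - self.high_window[0]
        if not np.isclose(ll, lh):
            raise ValueError("low and high windows must have equal length")
        lo, hi = sorted([self.low_window, self.high_window])
        if lo[1] > hi[0] + 1e-9:
            raise ValueError("windows must not overlap")

    @property
    def length_s(self) -> float:
        return self.low_window[1] - self.low_window[0]


def rating_auc(trace: RatingTrace) -> float:
    """Overall reported intensity: trapezoidal area under the rating trace,
    in scale-units x seconds."""
    if trace.samples.size < 2:
        raise ValueError("AUC needs at least 2 samples")
    return float(np.trapezoid(trace.samples, trace.times_s))


def median_trace(traces: Sequence[RatingTrace]) -> np.ndarray:
    """Pointwise median across subjects (mean-of-middle-two for even counts)."""
    if not traces:
        raise ValueError("no traces given")
    lengths = {t.samples.size for t in traces}
    rates = {t.rate_hz for t in traces}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError("all traces must share length and sampling rate")
    return np.median(np.vstack([t.samples for t in traces]), axis=0)


def _window_median(x: np.ndarray, start: int, length: int) -> float:
    return float(np.median(x[start : start + length]))


def _wilcoxon_p(high: np.ndarray, low: np.ndarray) -> float:
    diffs = high - low
    if np.all(diffs == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(high, low).pvalue)
    except ValueError:
        return 1.0


def find_epoch_pair(
    traces: Sequence[RatingTrace],
    alpha: float = 0.01,
    pairing: Literal["subjects", "timepoints"] = "subjects",
    min_length_samples: int = 10,
) -> EpochPair:
    """Search for the longest pair of equal-length, non-overlapping windows
    whose ratings differ at ``alpha`` by a Wilcoxon signed-rank test.

    Candidate lengths L descend from half the trace; at each L every
    non-overlapping start pair is a candidate.  Among pairs passing the
    Wilcoxon criterion, the pair maximizing (high-window median minus
    low-window median) on the group-median trace wins; ties break on the
    earliest high-window start, then the earliest low-window start.  The
    window with the larger median is the high-intensity epoch.

    ``pairing`` picks the Wilcoxon pairing unit: ``subjects`` (default)
    pairs per-subject window medians across subjects; ``timepoints`` pairs
    group-median samples by within-window position.

    Raises
    ------
    NoSeparableEpochsError
        If no candidate pair at any length passes the criterion.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    med = median_trace(traces)
    t = med.size
    rate = traces[0].rate_hz
    stacked = np.vstack([tr.samples for tr in traces])
    l0 = t // 2
    if l0 < max(min_length_samples, 2):
        raise ValueError("trace too short for any candidate window length")

    for length in range(l0, max(min_length_samples, 2) - 1, -1):
        # candidate (earlier, later) start pairs, ranked by group-median
        # separation so the first Wilcoxon pass is the max-difference winner
        starts = np.arange(0, t - 2 * length + 1)
        if starts.size == 0:
            continue
        meds = np.array([_window_median(med, s, length) for s in
                         range(0, t - length + 1)])
        cands: List[Tuple[float, int, int, int, int]] = []
        for a in starts:
            for b in range(a + length, t - length + 1):
                diff = meds[b] - meds[a]
                if diff == 0:
                    continue  # a zero-difference pair can never pass
                if diff > 0:
                    lo_s, hi_s = a, b
                else:
                    lo_s, hi_s = b, a
                cands.append((abs(diff), hi_s, lo_s, a, b))
        # descending difference; ties -> earliest high start, earliest low start
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        for diff, hi_s, lo_s, _, _ in cands:
            if pairing == "subjects":
                high = np.median(stacked[:, hi_s : hi_s + length], axis=1)
                low = np.median(stacked[:, lo_s : lo_s + length], axis=1)
            elif pairing == "timepoints":
                high = med[hi_s : hi_s + length]
                low = med[lo_s : lo_s + length]
            else:
                raise ValueError(f"unknown pairing mode {pairing!r}")
            p = _wilcoxon_p(high, low)
            if p < alpha:
                return EpochPair(
                    low_window=(float(lo_s / rate), float((lo_s + length) / rate)),
                    high_window=(float(hi_s / rate), float((hi_s + length) / rate)),
                    wilcoxon_p=float(p),
                    median_diff=float(diff),
                )
    raise NoSeparableEpochsError(
        f"no separable epochs: no window pair differs at p < {alpha}"
    )


def epochs_to_tr(
    pair: EpochPair, tr_seconds: float, lag_seconds: float = 0.0
) -> EpochPair:
    """Map second-space windows onto half-open TR-index windows.

    Each bound maps as floor((t + lag) / TR); if the two windows land on
    unequal TR counts the longer is truncated at its end.  A shared
    hemodynamic lag can shift both windows forward before mapping.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")

    def to_tr(win: Tuple[float, float]) -> Tuple[int, int]:
        a = int(np.floor((win[0] + lag_seconds) / tr_seconds))
        b = int(np.floor((win[1] + lag_seconds) / tr_seconds))
        return a, b

    lo = to_tr(pair.low_window)
    hi = to_tr(pair.high_window)
    n = min(lo[1] - lo[0], hi[1] - hi[0])
    if n < 3:
        raise ValueError(f"epoch maps to {n} volumes; need at least 3")
    lo = (lo[0], lo[0] + n)
    hi = (hi[0], hi[0] + n)
    return replace(pair, tr_windows={"low": lo, "high": hi, "n_volumes": n})
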