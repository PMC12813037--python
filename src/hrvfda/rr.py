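"""RR-interval cleaning and clock-aligned 5-minute segmentation.

An ambulatory recording arrives as one beat-indexed series per subject-day:
R-wave times (seconds since local midnight) and the preceding RR interval in
milliseconds.  Two things happen here before any spectral analysis:

* artifactual beats (ectopy, detection errors) are flagged against a local
  rolling median and either corrected by interpolation or, for long runs,
  excluded outright;
* the surviving beats are assigned to half-open clock-aligned 5-minute bins
  (288 per day, anchored at local midnight), producing per-epoch beat counts
  and interpolated fractions that drive the downstream validity rules.

Beats are processed in the beat domain (the tachogram), not resampled onto a
time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: number of 5-minute bins tiling a 24-h day
GRID_BINS = 288
#: epoch length in seconds
EPOCH_S = 300.0
#: seconds per day
DAY_S = 86400.0
#: a gap between consecutive beats exceeding the recorded interval by this
#: many seconds starts a new contiguous segment when beat times are rebuilt
GAP_TOL_S = 1.5


@dataclass
class RRSeries:
    """One subject-day of RR intervals.

    ``beat_time_s`` is the R-wave time of each beat (seconds since local
    midnight, strictly increasing); ``rr_ms`` is the interval ending at that
    beat.  ``interpolated`` marks beats whose interval was replaced during
    cleaning (or flagged as such in an input file).
    """

    subject_id: str
    day_index: int
    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.rr_ms.shape, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.beat_time_s.shape != self.rr_ms.shape:
            raise ValueError("beat_time_s and rr_ms must have equal length")
        if self.n and np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be positive")
        if self.n > 1 and np.any(np.diff(self.beat_time_s) <= 0):
            raise ValueError("beat_time_s must be strictly increasing")

    @property
    def n(self) -> int:
        return self.rr_ms.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "day_index": self.day_index,
                "beat_time_s": self.beat_time_s,
                "rr_ms": self.rr_ms,
                "interpolated": self.interpolated,
            }
        )


def rebuild_times(beat_time_s: np.ndarray, rr_ms: np.ndarray) -> np.ndarray:
    """Rebuild beat times cumulatively from intervals, segment by segment.

    Within a contiguous run of beats the new time of beat ``k`` is the time
    of the segment's first beat plus the cumulative sum of the subsequent
    intervals.  A new segment starts wherever the original inter-beat gap
    exceeds the recorded interval by more than :data:`GAP_TOL_S` (i.e. at
    wear gaps or where beats were excised), so genuine recording gaps are
    preserved rather than closed up.
    """
    t = np.asarray(beat_time_s, dtype=float)
    rr_s = np.asarray(rr_ms, dtype=float) / 1000.0
    if t.size == 0:
        return t.copy()
    gap = np.zeros(t.size, dtype=bool)
    gap[1:] = (np.diff(t) - rr_s[1:]) > GAP_TOL_S
    seg_id = np.cumsum(gap)
    cs = np.cumsum(rr_s)
    seg_starts = np.flatnonzero(np.r_[True, gap[1:]])
    seg_ends = np.r_[seg_starts[1:] - 1, t.size - 1]
    # anchors keep each segment's original start time, but never step back
    # behind the (possibly drifted) rebuilt end of the previous segment
    offsets = np.empty(seg_starts.size)
    prev_end = -np.inf
    for s, (i0, i1) in enumerate(zip(seg_starts, seg_ends)):
        anchor = max(t[i0], prev_end + rr_s[i0])
        offsets[s] = anchor - cs[i0]
        prev_end = offsets[s] + cs[i1]
    return offsets[seg_id] + cs


def _neighbor_median(rr_ms: np.ndarray, window: int) -> np.ndarray:
    """Median of the ``window`` nearest beats on each side, excluding self.

    Edges are reflect-padded.  Using neighbors on both sides (2*window
    values) keeps the reference robust to runs of up to ``window``
    consecutive corrupted beats.
    """
    w = int(window)
    padded = np.pad(rr_ms, w, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, 2 * w + 1)
    cols = np.r_[np.arange(w), np.arange(w + 1, 2 * w + 1)]
    return np.median(view[:, cols], axis=1)


def _run_lengths(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of True runs in a boolean mask."""
    if mask.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    padded = np.r_[False, mask, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


#: flagged runs longer than this many beats are excluded, not interpolated
MAX_INTERP_RUN = 3


def flag_and_interpolate(
    series: RRSeries,
    deviation_threshold: float = 0.2,
    window: int = 5,
) -> RRSeries:
    """Flag artifactual intervals and correct or excise them.

    A beat whose interval deviates from the local rolling median (see
    :func:`_neighbor_median`) by more than ``deviation_threshold`` (as a
    fraction of the median) is flagged.  Runs of up to
    :data:`MAX_INTERP_RUN` flagged beats are replaced by the rolling median
    and marked ``interpolated``; longer runs are dropped from the series.
    Beat times are rebuilt cumulatively afterwards (recording gaps are
    preserved, see :func:`rebuild_times`).

    Series shorter than ``window + 1`` beats are returned unchanged with a
    warning.
    """
    if series.n < window + 1:
        warnings.warn(
            f"series {series.subject_id} day {series.day_index}: "
            f"only {series.n} beats (< window+1), returned uncleaned",
            stacklevel=2,
        )
        return series

    rr = series.rr_ms
    ref = _neighbor_median(rr, window)
    flagged = np.abs(rr - ref) > deviation_threshold * ref

    keep = np.ones(series.n, dtype=bool)
    interp = series.interpolated.copy()
    rr_new = rr.copy()
    starts, lengths = _run_lengths(flagged)
    for s, ln in zip(starts, lengths):
        if ln > MAX_INTERP_RUN:
            keep[s : s + ln] = False
        else:
            rr_new[s : s + ln] = ref[s : s + ln]
            interp[s : s + ln] = True

    rr_k = rr_new[keep]
    t_k = rebuild_times(series.beat_time_s[keep], rr_k)
    return RRSeries(series.subject_id, series.day_index, t_k, rr_k, interp[keep])


def segment_epochs(series: RRSeries) -> pd.DataFrame:
    """Assign beats to half-open clock bins and summarise each epoch.

    Bin ``k`` holds beats with time in ``[300*k, 300*(k+1))``; a beat at
    exactly a boundary belongs to the later bin.  Bins outside ``[0, 86400)``
    or holding fewer than two beats produce no shell.  Returns one row per
    occupied epoch with ``n_beats`` and ``frac_interpolated``.
    """
    bins = np.floor_divide(series.beat_time_s, EPOCH_S).astype(int)
    inside = (bins >= 0) & (bins < GRID_BINS)
    b = bins[inside]
    counts = np.bincount(b, minlength=GRID_BINS)
    n_interp = np.bincount(b, weights=series.interpolated[inside].astype(float),
                           minlength=GRID_BINS)
    occupied = np.flatnonzero(counts >= 2)
    return pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "day_index": series.day_index,
            "bin": occupied,
            "n_beats": counts[occupied],
            "frac_interpolated": n_interp[occupied] / counts[occupied],
        }
    )


def epoch_slices(series: RRSeries) -> dict[int, slice]:
    """Index slice into the (time-sorted) series for each occupied bin."""
    bins = np.floor_divide(series.beat_time_s, EPOCH_S).astype(int)
    out: dict[int, slice] = {}
    edges = np.searchsorted(bins, np.arange(GRID_BINS + 1))
    for k in range(GRID_BINS):
        if edges[k + 1] - edges[k] >= 2:
            out[k] = slice(edges[k], edges[k + 1])
    return out


def epoch_validity(frac_interpolated, max_interp_frac: float = 0.2):
    """Epoch validity under the interpolated-fraction rule.

    An epoch is invalid when *more than* ``max_interp_frac`` of its beats
    required interpolation; equality is retained.
    """
    return np.asarray(frac_interpolated) <= max_interp_frac


def read_rr_csv(path) -> list[RRSeries]:
    """Read an RR CSV (subject_id, day_index, beat_time_s, rr_ms[, interpolated])."""
    df = pd.read_csv(path)
    out = []
    for (sid, day), grp in df.groupby(["subject_id", "day_index"], sort=True):
        grp = grp.sort_values("beat_time_s")
        interp = grp["interpolated"].to_numpy() if "interpolated" in grp else None
        out.append(
            RRSeries(str(sid), int(day), grp["beat_time_s"].to_numpy(),
                     grp["rr_ms"].to_numpy(), interp)
        )
    return out


def write_rr_csv(series_list: list[RRSeries], path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )
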