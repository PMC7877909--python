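"""Stimulus-aligned calcium-trace analysis (ΔF/F).

GCaMP fluorescence recorded around a brief optogenetic stimulus is
normalized to a pre-stimulus baseline, frames acquired while the imaging
shutter was closed (to protect the PMTs during LED illumination) are masked
as missing, and replicates are aligned so stimulus onset maps to t = 0
before averaging.

ΔF/F_t = (F_t − F0) / F0 with F0 the mean fluorescence over a baseline
window that must lie entirely before onset and outside the shutter-closed
interval.  Masked frames are NaN throughout and never enter F0, means, or
SEMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalciumTrace", "AlignedResponse", "dff", "align_average"]


@dataclass
class CalciumTrace:
    """One replicate: raw fluorescence, stimulus onset frame, shutter flags."""

    rep_id: str
    F: np.ndarray                  # a.u., >= 0
    onset_index: int               # frame of stimulus start
    fps: float
    shutter_closed: np.ndarray     # bool per frame

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.shutter_closed = np.asarray(self.shutter_closed, dtype=bool)
        if self.F.ndim != 1 or self.shutter_closed.shape != self.F.shape:
            raise ValueError("F and shutter_closed must be 1D and equal length")
        if not 0 <= self.onset_index < len(self.F):
            raise ValueError("onset_index out of range")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if np.nanmin(self.F) < 0:
            raise ValueError("fluorescence must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.F)


@dataclass
class AlignedResponse:
    """Replicate-averaged ΔF/F on a time axis relative to stimulus onset."""

    time: np.ndarray           # s, 0 at onset
    mean: np.ndarray           # NaN where all replicates are masked
    sem: np.ndarray            # NaN where < 2 replicates contribute
    n_per_timepoint: np.ndarray
    n_replicates: int
    masked_bounds: tuple[float, float] | None   # (s, s) shutter-closed span, if any


def _baseline_slice(trace: CalciumTrace, baseline_window: tuple[int, int]) -> slice:
    start, stop = baseline_window
    if stop <= start:
        raise ValueError("baseline window is empty")
    if start < 0 or stop > trace.onset_index:
        raise ValueError("baseline window must lie entirely before onset")
    if trace.shutter_closed[start:stop].any():
        raise ValueError("baseline window overlaps a shutter-closed frame")
    return slice(start, stop)


def dff(trace: CalciumTrace, baseline_window: tuple[int, int] | None = None) -> np.ndarray:
    """ΔF/F series; shutter-closed frames are NaN.

    ``baseline_window`` is a (start, stop) frame interval before onset;
    default is the 2 s immediately preceding onset.
    """
    if baseline_window is None:
        n_base = max(1, int(round(2.0 * trace.fps)))
        baseline_window = (max(0, trace.onset_index - n_base), trace.onset_index)
    sl = _baseline_slice(trace, baseline_window)
    f0 = float(trace.F[sl].mean())
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    out = (trace.F - f0) / f0
    out[trace.shutter_closed] = np.nan
    return out


def align_average(
    traces: list[CalciumTrace],
    baseline_window: tuple[int, int] | None = None,
) -> AlignedResponse:
    """ΔF/F-normalize, shift so onset is t = 0, trim to the common window,
    then mean and SEM per timepoint over the non-missing replicates."""
    if not traces:
        raise ValueError("need at least one trace")
    fps = traces[0].fps
    if any(t.fps != fps for t in traces):
        raise ValueError("traces must share fps")

    pre = min(t.onset_index for t in traces)
    post = min(t.n_frames - t.onset_index for t in traces)
    if pre + post < 1:
        raise ValueError("no common window across traces")

    rows = []
    shutter_rows = []
    for t in traces:
        sl = slice(t.onset_index - pre, t.onset_index + post)
        rows.append(dff(t, baseline_window)[sl])
        shutter_rows.append(t.shutter_closed[sl])
    mat = np.vstack(rows)

    n = np.sum(~np.isnan(mat), axis=0)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # all-masked timepoints legitimately yield NaN means
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.where(n > 0, np.nanmean(mat, axis=0), np.nan)
        sd = np.where(n > 1, np.nanstd(mat, axis=0, ddof=1), np.nan)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)

    time = (np.arange(-pre, post)) / fps
    masked_any = np.vstack(shutter_rows).any(axis=0)
    if masked_any.any():
        idx = np.nonzero(masked_any)[0]
        masked_bounds = (float(time[idx[0]]), float(time[idx[-1]]))
    else:
        masked_bounds = None
    return AlignedResponse(time=time, mean=mean, sem=sem, n_per_timepoint=n,
                           n_replicates=len(traces), masked_bounds=masked_bounds)
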