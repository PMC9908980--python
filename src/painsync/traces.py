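"""Raw ROI fluorescence -> ΔF/F0, integrated activity, active-soma calls.

The baseline F0 for each ROI is the mean over the contiguous 2-s window with
the lowest fluorescence anywhere in the recording; ΔF/F0 = (F − F0)/F0.
Integrated calcium activity is the plain sum of ΔF/F0 samples over the
analysis span (2.5 min by default), and a soma counts as active when its
peak ΔF/F0 exceeds three baseline standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "DffMatrix",
    "DegenerateBaselineError",
    "lowest_window_baseline",
    "compute_dff",
    "integrated_activity",
    "detect_active",
]


class DegenerateBaselineError(ValueError):
    """Baseline F0 <= 0: the ROI cannot be normalised."""


@dataclass
class TraceMatrix:
    """Raw fluorescence, frames x ROIs, with acquisition frame rate."""

    values: np.ndarray
    frame_rate_hz: float
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a frames x ROIs matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.values.shape[1] != len(self.roi_ids):
            raise ValueError("roi_ids length must match the ROI axis")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")
        if np.isnan(self.values).any():
            raise ValueError("fluorescence contains NaN")
        if (self.values < 0).any():
            raise ValueError("fluorescence must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class DffMatrix:
    """ΔF/F0 with per-ROI baseline bookkeeping.

    ``baseline_window_per_roi`` stores the half-open frame range
    ``(start, stop)`` of the selected lowest window; ``baseline_sd_per_roi``
    is the ΔF/F0 standard deviation inside that window (or the robust
    alternative, depending on how it was computed).
    """

    values: np.ndarray
    frame_rate_hz: float
    roi_ids: list[str]
    f0_per_roi: np.ndarray
    baseline_window_per_roi: list[tuple[int, int]]
    baseline_sd_per_roi: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _window_frames(window_s: float, frame_rate_hz: float) -> int:
    # round half up, minimum one frame
    return max(1, int(np.floor(window_s * frame_rate_hz + 0.5)))


def lowest_window_baseline(trace: np.ndarray, frame_rate_hz: float,
                           window_s: float = 2.0) -> tuple[float, tuple[int, int]]:
    """Minimum sliding-window mean of one fluorescence series.

    Scans every contiguous window of ``round(window_s * frame_rate_hz)``
    frames (step one frame) and returns ``(f0, (start, stop))`` for the
    window with the lowest mean.  Ties go to the earliest window.

    Raises
    ------
    ValueError
        If the series is shorter than one window.
    DegenerateBaselineError
        If the minimum window mean is not positive.
    """
    trace = np.asarray(trace, dtype=float)
    w = _window_frames(window_s, frame_rate_hz)
    if trace.size < w:
        raise ValueError(f"series of {trace.size} frames shorter than "
                         f"{w}-frame baseline window")
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    means = (csum[w:] - csum[:-w]) / w
    start = int(np.argmin(means))
    f0 = float(means[start])
    if not f0 > 0:
        raise DegenerateBaselineError(
            f"baseline F0 = {f0} is not positive")
    return f0, (start, start + w)


def compute_dff(traces: TraceMatrix, window_s: float = 2.0,
                sd_mode: str = "baseline_window") -> DffMatrix:
    """ΔF/F0 = (F − F0)/F0 per ROI, with per-ROI baseline statistics.

    Parameters
    ----------
    window_s
        Length of the lowest-fluorescence baseline window (default 2 s).
    sd_mode
        ``"baseline_window"`` (default): baseline SD is the sample SD of
        ΔF/F0 within the selected window — the literal reading of the
        active-soma criterion.  ``"robust"``: 1.4826 x MAD of ΔF/F0 over
        the full trace, useful because a 2-s window holds only ~3 frames
        at 1.3–1.7 Hz and its SD is noisy.

    Negative ΔF/F0 values are retained; the formula does not clip.
    """
    if sd_mode not in ("baseline_window", "robust"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    n_frames, n_rois = traces.values.shape
    dff = np.empty_like(traces.values)
    f0s = np.empty(n_rois)
    windows: list[tuple[int, int]] = []
    sds = np.empty(n_rois)
    for j in range(n_rois):
        col = traces.values[:, j]
        try:
            f0, win = lowest_window_baseline(col, traces.frame_rate_hz, window_s)
        except DegenerateBaselineError as exc:
            raise DegenerateBaselineError(
                f"ROI {traces.roi_ids[j]!r}: {exc}") from exc
        dff[:, j] = (col - f0) / f0
        f0s[j] = f0
        windows.append(win)
        if sd_mode == "baseline_window":
            seg = dff[win[0]:win[1], j]
            sds[j] = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
        else:
            med = np.median(dff[:, j])
            sds[j] = 1.4826 * float(np.median(np.abs(dff[:, j] - med)))
    return DffMatrix(values=dff, frame_rate_hz=traces.frame_rate_hz,
                     roi_ids=list(traces.roi_ids), f0_per_roi=f0s,
                     baseline_window_per_roi=windows, baseline_sd_per_roi=sds)


def _span_frames(dff: DffMatrix, duration_s: float) -> int:
    n = int(np.floor(duration_s * dff.frame_rate_hz))
    if n < 1:
        raise ValueError("duration_s spans no frames at this frame rate")
    if dff.n_frames < n:
        raise ValueError(
            f"recording has {dff.n_frames} frames but {n} are required to "
            f"cover {duration_s} s at {dff.frame_rate_hz} Hz")
    return n


def integrated_activity(dff: DffMatrix, duration_s: float = 150.0) -> np.ndarray:
    """Per-ROI sum of ΔF/F0 over the first ``duration_s`` seconds.

    The sum runs over ``floor(duration_s * frame_rate_hz)`` frames; a
    recording shorter than the span is an error, never silently truncated.
    """
    n = _span_frames(dff, duration_s)
    return dff.values[:n, :].sum(axis=0)


def detect_active(dff: DffMatrix, k: float = 3.0,
                  duration_s: float = 150.0) -> pd.DataFrame:
    """Active-soma calls plus per-ROI summary statistics.

    A ROI is active when its peak ΔF/F0 over the analysis span exceeds
    ``k`` baseline standard deviations.  A zero baseline SD marks a flat
    baseline: the ROI is active iff its trace is not constant.

    Returns a DataFrame indexed by roi_id with columns
    f0, baseline_sd, peak_dff, integrated_activity, is_active.
    """
    n = _span_frames(dff, duration_s)
    span = dff.values[:n, :]
    peak = span.max(axis=0)
    integ = span.sum(axis=0)
    active = np.empty(dff.n_rois, dtype=bool)
    for j in range(dff.n_rois):
        sd = dff.baseline_sd_per_roi[j]
        if sd > 0:
            active[j] = peak[j] > k * sd
        else:
            active[j] = bool(np.ptp(span[:, j]) > 0)
    return pd.DataFrame(
        {"f0": dff.f0_per_roi, "baseline_sd": dff.baseline_sd_per_roi,
         "peak_dff": peak, "integrated_activity": integ, "is_active": active},
        index=pd.Index(dff.roi_ids, name="roi_id"))
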