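"""ECoG power spectra: epoch-averaged FFT periodograms and band power.

Spectra are computed per epoch (10 s by default; 11.46 s matches sessions
recorded simultaneously with imaging, where 11.46 s = 10 imaging frames),
averaged, restricted to 0.5–40 Hz and normalised to relative power summing
to one.  Band summaries are the mean relative power density in the delta
(0.5–4 Hz), theta (4–8 Hz) and alpha (8–12 Hz) bands; band edges are
half-open [lo, hi), so 4 Hz belongs to theta and 8 Hz to alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "BANDS",
    "EcogRecording",
    "PsdResult",
    "power_spectrum",
    "band_mean",
    "power_behavior_correlation",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
}

_ANALYSIS_BAND = (0.5, 40.0)


@dataclass
class EcogRecording:
    """Single-channel ECoG with awake-resting epoch annotations.

    Epoch selection (no movement, no sleep) is an upstream annotation given
    as half-open ``[start_s, end_s)`` intervals; the analysis only consumes
    the annotated stretches.
    """

    samples: np.ndarray
    fs_hz: float = 5000.0
    epochs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not (self.fs_hz > 0):
            raise ValueError("fs_hz must be > 0")
        dur = self.samples.size / self.fs_hz
        prev_end = -np.inf
        for start, end in sorted(self.epochs):
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(f"epoch [{start}, {end}) outside record")
            if start < prev_end:
                raise ValueError("epoch annotations overlap")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class PsdResult:
    """Epoch-averaged relative power spectrum over 0.5–40 Hz.

    ``rel_power`` sums to one over the analysis band; ``abs_power`` keeps
    the pre-normalisation mean periodogram density (units^2/Hz) on the same
    grid, since it is not always clear which scale a downstream comparison
    wants.  ``total_power`` integrates the full-band density (all
    frequencies, not just 0.5–40 Hz) and approximates the mean epoch
    variance.
    """

    freqs: np.ndarray
    rel_power: np.ndarray
    abs_power: np.ndarray
    band_means: dict[str, float]
    epoch_len_s: float
    n_epochs: int
    total_power: float

    def band_mean(self, lo_hz: float, hi_hz: float) -> float:
        return band_mean(self, (lo_hz, hi_hz))


def _epoch_slices(rec: EcogRecording, epoch_len_s: float) -> list[slice]:
    """Carve each annotation into non-overlapping epochs of epoch_len_s."""
    n_ep = int(round(epoch_len_s * rec.fs_hz))
    out: list[slice] = []
    for start_s, end_s in rec.epochs:
        i0 = int(round(start_s * rec.fs_hz))
        i1 = int(round(end_s * rec.fs_hz))
        for s in range(i0, i1 - n_ep + 1, n_ep):
            out.append(slice(s, s + n_ep))
    return out


def power_spectrum(rec: EcogRecording, epoch_len_s: float = 10.0,
                   window: str = "hann") -> PsdResult:
    """Epoch-averaged FFT power spectrum, normalised over 0.5–40 Hz.

    Each epoch is mean-removed, windowed (Hann by default; ``"boxcar"``
    gives the raw rectangular periodogram) and its periodogram computed by
    FFT; periodograms are averaged across epochs with no overlap, then
    restricted to the 0.5–40 Hz analysis band and normalised so the
    relative power sums to one.

    Raises when no annotated epoch is long enough or the samples contain
    NaN.
    """
    if np.isnan(rec.samples).any():
        raise ValueError("samples contain NaN")
    slices = _epoch_slices(rec, epoch_len_s)
    if not slices:
        raise ValueError(
            f"no annotated epoch of at least {epoch_len_s} s available")
    psds = []
    for sl in slices:
        seg = rec.samples[sl]
        f, pxx = sps.periodogram(seg, fs=rec.fs_hz, window=window,
                                 detrend="constant", scaling="density")
        psds.append(pxx)
    mean_psd = np.mean(psds, axis=0)
    df = f[1] - f[0]
    total_power = float(np.sum(mean_psd) * df)

    lo, hi = _ANALYSIS_BAND
    mask = (f >= lo) & (f <= hi)
    freqs = f[mask]
    abs_power = mean_psd[mask]
    denom = abs_power.sum()
    if denom <= 0:
        raise ValueError("zero power inside the 0.5-40 Hz analysis band")
    rel_power = abs_power / denom

    result = PsdResult(freqs=freqs, rel_power=rel_power, abs_power=abs_power,
                       band_means={}, epoch_len_s=epoch_len_s,
                       n_epochs=len(slices), total_power=total_power)
    result.band_means = {name: band_mean(result, edges)
                         for name, edges in BANDS.items()}
    return result


def band_mean(psd: PsdResult, band: tuple[float, float]) -> float:
    """Mean relative power over bins with ``lo <= f < hi``."""
    lo, hi = band
    if not (_ANALYSIS_BAND[0] <= lo < hi <= _ANALYSIS_BAND[1]):
        raise ValueError(f"band [{lo}, {hi}) outside the analysis range")
    mask = (psd.freqs >= lo) & (psd.freqs < hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) is empty at the grid resolution")
    return float(psd.rel_power[mask].mean())


def power_behavior_correlation(values_x: np.ndarray,
                               values_y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of per-session scalars with its two-sided p-value.

    Intended for relating band power to behavioural thresholds or synchrony
    measures across sessions; the p-value comes from the t-distribution
    with n-2 degrees of freedom.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = spstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
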