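"""Pairwise synchrony of active ROIs with a circular-shift bootstrap null.

Synchrony is the Pearson correlation of ΔF/F0 between simultaneously imaged
cell pairs over a 150-s analysis span, active cells only.  Per-pair
significance comes from a surrogate null: one series of the pair is
circularly rotated by a random offset, the zero-lag correlation recomputed,
and after 500 shuffles a pair is significant when fewer than 5% of the
shuffles beat the observed value (strict inequality).  Circular rotation
preserves each trace's marginal values and autocorrelation, so the null
respects the slow indicator dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import DffMatrix

__all__ = [
    "SyncResult",
    "InsufficientPairsError",
    "pearson_matrix",
    "cross_correlogram",
    "circular_shift_significance",
    "significant_fraction",
    "compute_synchrony",
]


class InsufficientPairsError(ValueError):
    """Fewer than two active ROIs: no pairs to analyse."""


@dataclass
class SyncResult:
    """Pairwise synchrony summary for the active subpopulation.

    ``r_matrix`` is symmetric with unit diagonal over active ROIs; undefined
    entries (zero-variance traces) are NaN and excluded from
    ``mean_pairwise_r``.  ``pairs`` holds one row per unordered active pair
    (roi_a, roi_b, r, p_hat, significant); ``p_hat`` is NaN until the
    bootstrap has been run.
    """

    roi_ids: list[str]
    r_matrix: np.ndarray
    mean_pairwise_r: float
    pairs: pd.DataFrame
    n_shuffles: int | None = None
    alpha: float = 0.05
    seed: int | None = None

    @property
    def significant_fraction(self) -> float:
        return significant_fraction(self)


def _active_span(dff: DffMatrix, activity: pd.DataFrame,
                 span_s: float) -> tuple[np.ndarray, list[str]]:
    active_ids = [r for r in dff.roi_ids if bool(activity.loc[r, "is_active"])]
    if len(active_ids) < 2:
        raise InsufficientPairsError(
            f"only {len(active_ids)} active ROI(s); need >= 2")
    n = int(np.floor(span_s * dff.frame_rate_hz))
    if dff.n_frames < n:
        raise ValueError(f"recording has {dff.n_frames} frames; "
                         f"{n} needed for a {span_s}-s span")
    cols = [dff.roi_ids.index(r) for r in active_ids]
    return dff.values[:n, cols], active_ids


def pearson_matrix(dff: DffMatrix, activity: pd.DataFrame,
                   span_s: float = 150.0) -> SyncResult:
    """Pearson correlation matrix over all active ROI pairs.

    Zero-variance traces give NaN off-diagonal entries, reported as missing
    and excluded from ``mean_pairwise_r`` (the mean of the strict upper
    triangle).
    """
    x, ids = _active_span(dff, activity, span_s)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    r = (r + r.T) / 2.0  # enforce exact symmetry against fp asymmetry
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    iu = np.triu_indices(len(ids), k=1)
    upper = r[iu]
    mean_r = float(np.nanmean(upper)) if np.isfinite(upper).any() else float("nan")
    pairs = pd.DataFrame({
        "roi_a": [ids[i] for i in iu[0]],
        "roi_b": [ids[j] for j in iu[1]],
        "r": upper,
        "p_hat": np.nan,
        "significant": pd.array([pd.NA] * len(upper), dtype="boolean"),
    })
    return SyncResult(roi_ids=ids, r_matrix=r, mean_pairwise_r=mean_r,
                      pairs=pairs)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def cross_correlogram(x: np.ndarray, y: np.ndarray,
                      max_lag_frames: int) -> pd.Series:
    """Pearson correlation of overlapping segments at each integer lag.

    The value at lag ``l`` correlates ``x[t]`` with ``y[t - l]`` over the
    overlap, so when x is a copy of y delayed by l0 frames the correlogram
    peaks at ``l = l0``; lag 0 reproduces the plain Pearson coefficient.
    Zero-variance overlaps yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    t = x.size
    if not 0 <= max_lag_frames < t:
        raise ValueError("max_lag_frames must lie in [0, len-1]")
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    vals = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            vals[i] = _pearson(x[lag:], y[:t - lag])
        else:
            vals[i] = _pearson(x[:t + lag], y[-lag:])
    return pd.Series(vals, index=pd.Index(lags, name="lag_frames"),
                     name="r")


def circular_shift_significance(x: np.ndarray, y: np.ndarray,
                                n_shuffles: int = 500, alpha: float = 0.05,
                                seed: int | None = None,
                                rng: np.random.Generator | None = None,
                                ) -> tuple[float, bool]:
    """Circular-shift bootstrap for the zero-lag correlation of one pair.

    Each shuffle rotates ``y`` circularly by an offset drawn uniformly from
    ``{1, ..., T-1}`` (never 0, so the surrogate is always displaced) and
    recomputes the zero-lag Pearson correlation.  ``p_hat`` is the fraction
    of shuffles whose value is strictly greater than the observed one; ties
    count for the observed data.  The pair is significant when
    ``p_hat < alpha``.  Constant series carry no correlation structure and
    return ``(1.0, False)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    t = x.size
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0, False
    if rng is None:
        rng = np.random.default_rng(seed)
    x0 = (x - x.mean()) / sx
    y0 = (y - y.mean()) / sy
    observed = float((x0 * y0).mean())
    offsets = rng.integers(1, t, size=n_shuffles)
    # rotation preserves mean and SD, so only the cross term changes
    idx = (np.arange(t)[None, :] - offsets[:, None]) % t
    shuffled = (y0[idx] @ x0) / t
    p_hat = float(np.count_nonzero(shuffled > observed) / n_shuffles)
    return p_hat, bool(p_hat < alpha)


def significant_fraction(sync: SyncResult) -> float:
    """Proportion of valid pairs called significant by the bootstrap."""
    sig = sync.pairs["significant"]
    valid = sig.notna() & sync.pairs["r"].notna()
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pairs with computed significance")
    return float(sig[valid].astype(bool).sum() / n_valid)


def compute_synchrony(dff: DffMatrix, activity: pd.DataFrame,
                      span_s: float = 150.0, n_shuffles: int = 500,
                      alpha: float = 0.05, seed: int = 0) -> SyncResult:
    """Full pairwise analysis: correlation matrix plus per-pair bootstrap.

    One RNG seeded with ``seed`` drives every pair's shuffles in pair order,
    so the whole result is reproducible from the seed.
    """
    sync = pearson_matrix(dff, activity, span_s)
    x, ids = _active_span(dff, activity, span_s)
    rng = np.random.default_rng(seed)
    p_hats, sigs = [], []
    for row in sync.pairs.itertuples(index=False):
        a, b = ids.index(row.roi_a), ids.index(row.roi_b)
        if np.isnan(row.r):
            p_hats.append(float("nan"))
            sigs.append(pd.NA)
            continue
        p, s = circular_shift_significance(x[:, a], x[:, b],
                                           n_shuffles=n_shuffles,
                                           alpha=alpha, rng=rng)
        p_hats.append(p)
        sigs.append(s)
    sync.pairs["p_hat"] = p_hats
    sync.pairs["significant"] = pd.array(sigs, dtype="boolean")
    sync.n_shuffles = n_shuffles
    sync.alpha = alpha
    sync.seed = seed
    return sync
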