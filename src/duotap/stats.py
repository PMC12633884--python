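"""Inter-tap intervals, asynchronies and windowed detrended cross-correlation.

All statistics are reported in milliseconds (timelines store seconds).

The windowed detrended cross-correlation (WDCC) slides a short window along
a pair of interval series, removes each window's least-squares linear trend,
correlates the residuals (Pearson), and averages the coefficient across
windows separately for every lag.  The lag sign convention: a *positive* lag
``l`` correlates ``x`` at window position ``n`` with ``y`` at ``n + l``
(``y`` lagging ``x``).  The characteristic mutual-adaptation signature of
coupled tapping is a negative coefficient at lag 0 with positive peaks at
lag ±1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .model import PairTimeline

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 10
DEFAULT_WINDOW_LEN = 15
DEFAULT_WINDOW_STEP = 1

# residual sum-of-squares below this (relative to the raw segment scale)
# marks a zero-variance detrended segment
_VAR_RTOL = 1e-18


@dataclass(frozen=True)
class ITISeries:
    """Ordered inter-tap intervals of one player, milliseconds."""

    values: np.ndarray
    player: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class AsynchronySeries:
    """Signed per-tap timing differences, player 1 minus player 2, ms."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class WDCCProfile:
    """Per-lag WDCC coefficients with the window settings that produced them."""

    lags: np.ndarray
    coefficients: np.ndarray
    window_len: int
    window_step: int
    n_windows: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=int))
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        object.__setattr__(self, "n_windows", np.asarray(self.n_windows, dtype=int))

    def coefficient_at(self, lag: int) -> float:
        (pos,) = np.nonzero(self.lags == lag)[0]
        return float(self.coefficients[pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "coefficient": self.coefficients,
                "n_windows": self.n_windows,
            }
        )


@dataclass(frozen=True)
class SummaryStats:
    """Group mean ± SD (across stimuli) of per-stimulus timing statistics, ms."""

    mean_iti_p1: tuple[float, float]
    sd_iti_p1: tuple[float, float]
    mean_iti_p2: tuple[float, float]
    sd_iti_p2: tuple[float, float]
    mean_async: tuple[float, float]
    sd_async: tuple[float, float]
    n_stimuli: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for player, mi, si in (
            (1, self.mean_iti_p1, self.sd_iti_p1),
            (2, self.mean_iti_p2, self.sd_iti_p2),
        ):
            rows.append(
                {
                    "player": player,
                    "mean_iti": mi[0],
                    "mean_iti_sd": mi[1],
                    "sd_iti": si[0],
                    "sd_iti_sd": si[1],
                    "mean_async": self.mean_async[0] if player == 1 else -self.mean_async[0],
                    "mean_async_sd": self.mean_async[1],
                    "sd_async": self.sd_async[0],
                    "sd_async_sd": self.sd_async[1],
                }
            )
        return pd.DataFrame(rows)


def plot_wdcc(profile: WDCCProfile, ax=None, **kwargs):
    """Lag-profile plot of a WDCC profile (stem style, zero line)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(profile.lags, profile.coefficients, marker="o", **kwargs)
    ax.set_xlabel("lag (taps)")
    ax.set_ylabel("WDCC coefficient")
    ax.set_ylim(-1, 1)
    return ax


class UndefinedCoefficientError(ValueError):
    """Every window at some lag had a zero-variance detrended segment."""


def compute_iti(timeline: PairTimeline, player: int) -> ITISeries:
    """First-order differences of one player's tap times, in ms."""
    taps = timeline.taps(player)
    if len(taps) < 2:
        raise ValueError("need at least 2 taps to form intervals")
    diffs = np.diff(taps)
    if np.any(diffs <= 0):
        raise ValueError("tap times are not strictly increasing")
    return ITISeries(values=diffs * 1e3, player=player)


def compute_asynchrony(timeline: PairTimeline) -> AsynchronySeries:
    """Per-tap asynchrony a_n = t_n(1) − t_n(2), in ms."""
    if len(timeline.taps_p1) != len(timeline.taps_p2):
        raise ValueError("players have unequal tap counts")
    return AsynchronySeries(values=(timeline.taps_p1 - timeline.taps_p2) * 1e3)


def mean_timing(timeline: PairTimeline) -> np.ndarray:
    """Average tap-time series m_n = (t_n(1) + t_n(2)) / 2, in ms."""
    if len(timeline.taps_p1) != len(timeline.taps_p2):
        raise ValueError("players have unequal tap counts")
    return (timeline.taps_p1 + timeline.taps_p2) * 0.5e3


def _detrend_projection(w: int) -> np.ndarray:
    """Projection matrix removing the least-squares line from a length-w segment."""
    A = np.column_stack([np.ones(w), np.arange(w, dtype=float)])
    return np.eye(w) - A @ np.linalg.pinv(A)


def wdcc_batch(
    X: np.ndarray,
    Y: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
) -> tuple[np.ndarray, np.ndarray]:
    """WDCC of ``B`` series pairs at once.

    ``X`` and ``Y`` have shape ``(B, N)``.  Returns ``(coefs, n_windows)``
    with shapes ``(B, 2·max_lag+1)``; lags run −max_lag..+max_lag.  Windows
    whose detrended segment has zero variance are excluded from the average
    (their count is reflected in ``n_windows``); a lag where every window is
    excluded yields NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    B, N = X.shape
    w = window_len
    if w + max_lag > N:
        raise ValueError(
            f"window_len + max_lag = {w + max_lag} exceeds series length {N}"
        )
    P = _detrend_projection(w)
    Xw = sliding_window_view(X, w, axis=1)  # (B, N-w+1, w)
    Yw = sliding_window_view(Y, w, axis=1)
    # detrended residuals of every window (residuals are mean-zero)
    RX = Xw @ P
    RY = Yw @ P
    vX = np.einsum("bnw,bnw->bn", RX, RX)
    vY = np.einsum("bnw,bnw->bn", RY, RY)
    scaleX = np.maximum(np.einsum("bnw,bnw->bn", Xw, Xw), 1.0)
    scaleY = np.maximum(np.einsum("bnw,bnw->bn", Yw, Yw), 1.0)
    okX = vX > _VAR_RTOL * scaleX
    okY = vY > _VAR_RTOL * scaleY

    lags = np.arange(-max_lag, max_lag + 1)
    coefs = np.full((B, lags.size), np.nan)
    n_windows = np.zeros((B, lags.size), dtype=int)
    for li, lag in enumerate(lags):
        i0 = max(0, -lag)
        i1 = N - w - max(0, lag)  # inclusive last start
        starts = np.arange(i0, i1 + 1, window_step)
        if starts.size == 0:
            continue
        sx, sy = starts, starts + lag
        num = np.einsum("bnw,bnw->bn", RX[:, sx], RY[:, sy])
        denom = vX[:, sx] * vY[:, sy]
        ok = okX[:, sx] & okY[:, sy]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(denom)
        cnt = ok.sum(axis=1)
        n_windows[:, li] = cnt
        total = np.where(ok, r, 0.0).sum(axis=1)
        coefs[:, li] = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
        dropped = starts.size - cnt
        if np.any(dropped):
            logger.debug(
                "lag %d: dropped %d zero-variance windows across %d series",
                lag,
                int(dropped.sum()),
                B,
            )
    return coefs, n_windows


def wdcc(
    x: ITISeries | np.ndarray,
    y: ITISeries | np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
) -> WDCCProfile:
    """Windowed detrended cross-correlation profile of two interval series.

    Raises :class:`UndefinedCoefficientError` when some lag has no window
    with nonzero residual variance in both segments.
    """
    xv = x.values if isinstance(x, ITISeries) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, ITISeries) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("series lengths differ")
    coefs, n_win = wdcc_batch(
        xv[None, :], yv[None, :], max_lag=max_lag, window_len=window_len,
        window_step=window_step,
    )
    lags = np.arange(-max_lag, max_lag + 1)
    if np.any(n_win[0] == 0):
        bad = lags[n_win[0] == 0]
        raise UndefinedCoefficientError(
            f"all windows excluded (zero variance) at lags {bad.tolist()}"
        )
    return WDCCProfile(
        lags=lags,
        coefficients=coefs[0],
        window_len=window_len,
        window_step=window_step,
        n_windows=n_win[0],
    )


def timeline_wdcc(
    timeline: PairTimeline,
    max_lag: int = DEFAULT_MAX_LAG,
    window_len: int = DEFAULT_WINDOW_LEN,
    window_step: int = DEFAULT_WINDOW_STEP,
) -> WDCCProfile:
    """WDCC of the two players' ITI series of one timeline."""
    return wdcc(
        compute_iti(timeline, 1),
        compute_iti(timeline, 2),
        max_lag=max_lag,
        window_len=window_len,
        window_step=window_step,
    )


def _timelines_of(stimulus_set) -> Sequence[PairTimeline]:
    tls = getattr(stimulus_set, "timelines", stimulus_set)
    return list(tls)


def exact_mean_sd(values: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """Mean and SD via correctly-rounded summation (``math.fsum``).

    Correct rounding makes the results invariant under permutation of the
    values, so statistics of shuffled surrogates match their source's
    bit-for-bit.
    """
    import math

    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = math.fsum(arr) / n
    if n <= ddof:
        return mean, 0.0
    var = math.fsum((arr - mean) ** 2) / (n - ddof)
    return mean, math.sqrt(var)


def summarize_set(stimulus_set: Iterable[PairTimeline]) -> SummaryStats:
    """Group mean ± SD, across stimuli, of per-stimulus ITI/asynchrony stats.

    Mirrors the descriptive-table convention: per stimulus compute the mean
    and SD of each player's ITIs and of the player-1 asynchrony series, then
    aggregate mean ± SD over stimuli (sample SD, ddof=1).
    """
    timelines = _timelines_of(stimulus_set)
    if not timelines:
        raise ValueError("empty stimulus set")
    per = {k: [] for k in ("mi1", "si1", "mi2", "si2", "ma", "sa")}
    for tl in timelines:
        i1 = compute_iti(tl, 1).values
        i2 = compute_iti(tl, 2).values
        a = compute_asynchrony(tl).values
        m1, s1 = exact_mean_sd(i1)
        m2, s2 = exact_mean_sd(i2)
        ma, sa = exact_mean_sd(a)
        per["mi1"].append(m1)
        per["si1"].append(s1)
        per["mi2"].append(m2)
        per["si2"].append(s2)
        per["ma"].append(ma)
        per["sa"].append(sa)

    def agg(v: list) -> tuple[float, float]:
        return exact_mean_sd(np.asarray(v))

    return SummaryStats(
        mean_iti_p1=agg(per["mi1"]),
        sd_iti_p1=agg(per["si1"]),
        mean_iti_p2=agg(per["mi2"]),
        sd_iti_p2=agg(per["si2"]),
        mean_async=agg(per["ma"]),
        sd_async=agg(per["sa"]),
        n_stimuli=len(timelines),
    )
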