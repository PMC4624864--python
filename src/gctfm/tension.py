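"""Axon-tension (net-force) time series and its fluctuation statistics.

The traction maps give a direct dynamic readout of the tension carried by
the axon: F(t) = |net traction force| per frame.  Its fluctuations are
characterized by the normalized autocorrelation

    R(τ) = ⟨(F(t) − μ)(F(t + τ) − μ)⟩ / σ²,

fit to an exponential decay over a fixed lag window, and by the mean
squared displacement of the signal,

    MSD(τ) = ⟨(F(t + τ) − F(t))²⟩,

normalized by μ² and fit to a power law over a fixed window.  Averages run
over all available time origins at each lag; lags are integer multiples of
Δt only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fields import TractionMap, net_force

__all__ = [
    "TensionSeries",
    "AutocorrelationResult",
    "MsdResult",
    "tension_series",
    "autocorrelation",
    "fit_autocorr_decay",
    "msd",
    "fit_msd_exponent",
]

#: default maximum autocorrelation lag (s)
MAX_LAG_AUTOCORR = 480.0
#: default maximum MSD lag (s)
MAX_LAG_MSD = 900.0
#: default exponential-fit window for R(τ) (s)
AUTOCORR_FIT_WINDOW = (10.0, 80.0)
#: default power-law fit window for the MSD (s)
MSD_FIT_WINDOW = (2.0, 200.0)


@dataclass
class TensionSeries:
    """Net-force magnitude per frame (nN) at constant Δt (s)."""

    F: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, float)
        if self.F.ndim != 1 or self.F.size < 2:
            raise ValueError("need a 1D series of at least two frames")
        if np.any(self.F < 0):
            raise ValueError("tension magnitudes must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.F.mean())

    @property
    def std(self) -> float:
        return float(self.F.std())

    @property
    def duration(self) -> float:
        return (self.F.size - 1) * self.dt


def tension_series(
    maps: Sequence[TractionMap], dt: Optional[float] = None
) -> TensionSeries:
    """F(t) = |net force| of each traction map, in nN."""
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    ref = maps[0]
    for tm in maps[1:]:
        if not tm.congruent(ref):
            raise ValueError("maps must share one grid")
    if dt is None:
        dts = np.diff([tm.t for tm in maps])
        if not np.allclose(dts, dts[0]):
            raise ValueError("frame interval must be constant")
        dt = float(dts[0])
    F = np.array([np.linalg.norm(net_force(tm)) for tm in maps])
    return TensionSeries(F=F, dt=dt)


@dataclass
class AutocorrelationResult:
    lags: np.ndarray      # s
    R: np.ndarray
    window: tuple[float, float] = AUTOCORR_FIT_WINDOW
    decay_time: Optional[float] = None


def autocorrelation(
    series: TensionSeries, max_lag: float = MAX_LAG_AUTOCORR
) -> AutocorrelationResult:
    """Normalized autocorrelation R(τ) for lags up to ``max_lag``.

    The biased autocovariance estimator is used (sum of centered products
    over all available time origins, divided by the full series length n),
    normalized by the series variance, so R(0) = 1 exactly and the white
    noise sampling fluctuation stays below ~1/sqrt(n) at every lag.
    """
    F = series.F
    mu = F.mean()
    var = F.var()
    if var <= 0:
        raise ValueError("autocorrelation undefined for a constant series")
    n = F.size
    kmax = min(int(max_lag / series.dt), n - 2)
    d = F - mu
    R = np.empty(kmax + 1)
    for k in range(kmax + 1):
        R[k] = np.sum(d[: n - k] * d[k:]) / (n * var)
    return AutocorrelationResult(lags=series.dt * np.arange(kmax + 1), R=R)


def fit_autocorr_decay(
    result: AutocorrelationResult,
    window: tuple[float, float] = AUTOCORR_FIT_WINDOW,
) -> float:
    """Exponential decay time (s) from a log-linear fit of R(τ).

    Uses lags inside the window with R > 0 (negative excursions are
    excluded from the fit but reported in the result); requires at least
    three such lags and a negative slope.
    """
    sel = (
        (result.lags >= window[0])
        & (result.lags <= window[1])
        & (result.R > 0)
    )
    if sel.sum() < 3:
        raise ValueError("need at least three positive R values in the window")
    slope, _ = np.polyfit(result.lags[sel], np.log(result.R[sel]), 1)
    if slope >= 0:
        raise ValueError("no decay: non-negative slope in the fit window")
    decay = -1.0 / slope
    result.window = window
    result.decay_time = decay
    return decay


@dataclass
class MsdResult:
    lags: np.ndarray      # s (lag 0 included, MSD(0) = 0)
    msd: np.ndarray       # normalized by μ² when ``normalized``
    normalized: bool
    window: tuple[float, float] = MSD_FIT_WINDOW
    exponent: Optional[float] = None


def msd(
    series: TensionSeries,
    max_lag: float = MAX_LAG_MSD,
    normalize: bool = True,
) -> MsdResult:
    """Mean squared increment of the tension per lag.

    Lags run to ``max_lag`` but never beyond half the series duration
    (clipped with a warning).  With ``normalize`` the curve is divided by
    μ², making saturation values > 1 the signature of fluctuations larger
    than the mean.
    """
    F = series.F
    n = F.size
    half = series.duration / 2.0
    if max_lag > half + 1e-9:
        warnings.warn(
            f"max_lag {max_lag:g}s exceeds half the duration; clipped to {half:g}s"
        )
        max_lag = half
    kmax = int(max_lag / series.dt)
    out = np.empty(kmax + 1)
    out[0] = 0.0
    for k in range(1, kmax + 1):
        diff = F[k:] - F[: n - k]
        out[k] = np.mean(diff ** 2)
    if normalize:
        mu = F.mean()
        if mu == 0:
            raise ValueError("cannot normalize by a zero mean")
        out = out / mu ** 2
    return MsdResult(
        lags=series.dt * np.arange(kmax + 1), msd=out, normalized=normalize
    )


def fit_msd_exponent(
    result: MsdResult, window: tuple[float, float] = MSD_FIT_WINDOW
) -> float:
    """Power-law exponent from the log-log slope of the MSD in the window.

    Non-positive MSD values (and lag 0) are excluded; at least three lags
    must remain.
    """
    sel = (
        (result.lags >= window[0])
        & (result.lags <= window[1])
        & (result.msd > 0)
        & (result.lags > 0)
    )
    if sel.sum() < 3:
        raise ValueError("need at least three positive MSD values in the window")
    slope, _ = np.polyfit(
        np.log(result.lags[sel]), np.log(result.msd[sel]), 1
    )
    result.window = window
    result.exponent = float(slope)
    return float(slope)
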