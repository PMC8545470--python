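"""Corrective-growth statistics, stage summaries, and growth rate.

The corrective (self-correcting) growth signature is a negative correlation
between the thickness deviations of adjacent tablets: a tablet grown thick
tends to be followed by a thin one. Deviations are taken from the centered
rolling mean of width three (including self),

    dev_N = w_N - (w_{N-1} + w_N + w_{N+1}) / 3
          = (2 w_N - w_{N-1} - w_{N+1}) / 3,

and the lag-1 Pearson correlation of (dev_N, dev_{N+1}) is reported with its
least-squares slope, R^2 and two-sided t-test p-value.

Caution — estimator bias: because the rolling mean includes the center
sample, dev is a moving-average filter of the thickness sequence, and for
*uncorrelated* thicknesses the lag-1 deviation correlation is exactly -2/3
(coefficients (-1, 2, -1)/3: cross-covariance -4/9, variance 6/9). A
measured value near -0.66 therefore cannot, by itself, demonstrate
corrective growth. :func:`detrended_lag1_autocorrelation` provides a
companion estimator (direct lag-1 autocorrelation after a long-wavelength
high-pass) whose null value is near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profile import ThicknessProfile

__all__ = [
    "DeviationSeries",
    "AdjacentCorrelation",
    "StageSummary",
    "GrowthRate",
    "rolling_deviation",
    "adjacent_correlation",
    "detrended_lag1_autocorrelation",
    "stage_statistics",
    "growth_rate",
]


@dataclass
class DeviationSeries:
    """dev_N (nm) for interior layers, with the source layer index."""

    layer_index: np.ndarray  # 1-based N for each deviation
    dev: np.ndarray


@dataclass
class AdjacentCorrelation:
    r: float
    r_squared: float
    p_value: float
    slope: float
    n_pairs: int


@dataclass
class StageSummary:
    label: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    mean_nm: float
    sd_nm: float
    n: int


@dataclass
class GrowthRate:
    tablets_per_day: float
    microns_per_day: float


def rolling_deviation(profile: ThicknessProfile) -> DeviationSeries:
    """dev_N = w_N - rolling mean of (w_{N-1}, w_N, w_{N+1}); endpoints dropped.

    Flagged layers create gaps: a deviation is only computed where the layer
    and both neighbors are unflagged, and no downstream pair spans a gap.
    The deviation is exactly invariant under adding a constant or a linear
    trend to the thicknesses.
    """
    w = profile.thickness_nm
    if w.size < 3:
        raise ValueError("profile must contain at least 3 layers")
    ok = profile.ok_mask
    dev = (2.0 * w[1:-1] - w[:-2] - w[2:]) / 3.0
    valid = ok[1:-1] & ok[:-2] & ok[2:]
    idx = np.arange(2, w.size)  # 1-based N of the center layer (2..L-1)
    return DeviationSeries(layer_index=idx[valid], dev=dev[valid])


def adjacent_correlation(devs: DeviationSeries) -> AdjacentCorrelation:
    """Pearson correlation of (dev_N, dev_{N+1}) with LS slope and t-test p.

    Only consecutive deviations (layer indices differing by 1) form pairs,
    so gaps from excluded layers are respected.
    """
    consecutive = np.diff(devs.layer_index) == 1
    a = devs.dev[:-1][consecutive]
    b = devs.dev[1:][consecutive]
    if a.size < 10:
        raise ValueError("need at least 10 adjacent deviation pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate deviations: zero variance")
    res = stats.linregress(a, b)
    return AdjacentCorrelation(
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        n_pairs=int(a.size),
    )


def detrended_lag1_autocorrelation(
    profile: ThicknessProfile, highpass_window: int = 25
) -> float:
    """Lag-1 autocorrelation of thickness after removing a rolling mean.

    The long-wavelength environmental drift is removed with a centered
    rolling mean of ``highpass_window`` tablets (the scale separating the
    1/f regime from the corrective regime); the remaining short-range signal
    is then autocorrelated directly. Under uncorrelated growth this
    estimator is near zero, unlike the rolling-mean-of-three deviation
    correlation whose null value is -2/3.
    """
    w = profile.thickness_nm[profile.ok_mask]
    if w.size < 3 * highpass_window:
        raise ValueError("profile too short for the high-pass window")
    kernel = np.ones(highpass_window) / highpass_window
    trend = np.convolve(w, kernel, mode="same")
    half = highpass_window // 2
    resid = (w - trend)[half:-half]
    r = np.corrcoef(resid[:-1], resid[1:])[0, 1]
    return float(r)


def stage_statistics(
    profile: ThicknessProfile,
    windows: list[tuple[int, int]],
    labels: list[str] | None = None,
) -> list[StageSummary]:
    """Per-window mean and SD of unflagged thicknesses (1-based, inclusive)."""
    out = []
    labels = labels or [f"stage{i+1}" for i in range(len(windows))]
    for (a, b), lab in zip(windows, labels):
        if not (1 <= a <= b <= len(profile)):
            raise ValueError(f"window ({a}, {b}) outside profile of length {len(profile)}")
        sel = profile.thickness_nm[a - 1 : b][profile.ok_mask[a - 1 : b]]
        if sel.size == 0:
            raise ValueError(f"window ({a}, {b}) contains no usable layers")
        out.append(
            StageSummary(
                label=lab,
                start=a,
                end=b,
                mean_nm=float(sel.mean()),
                sd_nm=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                n=int(sel.size),
            )
        )
    return out


def growth_rate(n_layers: int, days: float, mean_thickness_nm: float) -> GrowthRate:
    """Tablets/day = layer count / lifetime; microns/day scales by thickness."""
    if days <= 0:
        raise ValueError(f"lifetime in days must be > 0, got {days}")
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    tpd = n_layers / days
    return GrowthRate(
        tablets_per_day=tpd,
        microns_per_day=tpd * mean_thickness_nm * 1e-3,
    )
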