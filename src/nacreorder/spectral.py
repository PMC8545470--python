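"""Power spectral density of thickness profiles and 1/f^alpha exponent fits.

Frequency is in cycles per tablet (f = 1 / number of tablets). The PSD is
Bartlett-averaged: the profile is split into contiguous equal segments
(default 10), each linearly detrended, and the one-sided periodograms are
averaged — the single-profile analogue of averaging over neighboring
regions, needed because a raw periodogram is not a consistent estimator.

The 1/f exponent alpha is the negative slope of a degree-1 least-squares
fit of log10 power versus log10 frequency over the fit band (default
0.0004 < f < 0.04, i.e. 25 to 2,500 tablets). Above the band the corrective
(negatively autocorrelated) growth flattens and then raises the spectrum;
:func:`detect_flattening` classifies that high-frequency slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .profile import ThicknessProfile

__all__ = [
    "SpectralEstimate",
    "psd",
    "psd_transects",
    "fit_powerlaw",
    "detect_flattening",
    "DEFAULT_BAND",
]

DEFAULT_BAND = (0.0004, 0.04)


@dataclass
class SpectralEstimate:
    f: np.ndarray  # cycles per tablet, > 0
    power: np.ndarray  # nm^2 per unit frequency, one-sided
    n_segments: int
    segment_length: int
    alpha: float | None = None
    alpha_stderr: float | None = None
    band: tuple[float, float] | None = None
    high_f_slope: float | None = None
    high_f_class: str | None = None


def _segment_psd(segments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average one-sided periodograms of linearly detrended rows.

    Per-segment linear detrending suppresses leakage of power from
    wavelengths longer than a segment (which would otherwise bias steep
    power-law slopes); no taper is applied.
    """
    nseg, slen = segments.shape
    seg = signal.detrend(segments.astype(float), axis=1, type="linear")
    spec = np.fft.rfft(seg, axis=1)
    p = (spec.real**2 + spec.imag**2) / slen
    # one-sided: double interior bins (DC dropped; Nyquist not doubled)
    p[:, 1 : (slen + 1) // 2] *= 2.0
    power = p.mean(axis=0)[1:]
    f = np.fft.rfftfreq(slen, d=1.0)[1:]
    return f, power


def psd(profile: ThicknessProfile | np.ndarray, n_segments: int = 10) -> SpectralEstimate:
    """Bartlett-averaged one-sided PSD over ``n_segments`` contiguous segments.

    Unit spacing is one tablet, so Parseval holds as
    sum(power) * df = mean segment variance.
    """
    w = profile.thickness_nm if isinstance(profile, ThicknessProfile) else np.asarray(profile, float)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    min_len = 4 * n_segments
    if w.size < min_len:
        raise ValueError(
            f"profile of {w.size} tablets is too short: need at least {min_len} "
            f"for {n_segments} segments"
        )
    slen = w.size // n_segments
    segs = w[: slen * n_segments].reshape(n_segments, slen)
    f, power = _segment_psd(segs)
    return SpectralEstimate(f=f, power=power, n_segments=n_segments, segment_length=slen)


def psd_transects(profiles: list[np.ndarray]) -> SpectralEstimate:
    """PSD averaged across parallel transect profiles (trimmed to equal length).

    Alternative averaging mode: one periodogram per transect instead of
    contiguous segments of a single long profile.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    slen = min(len(p) for p in profiles)
    if slen < 4:
        raise ValueError("profiles too short")
    segs = np.stack([np.asarray(p, float)[:slen] for p in profiles])
    f, power = _segment_psd(segs)
    return SpectralEstimate(f=f, power=power, n_segments=len(profiles), segment_length=slen)


def fit_powerlaw(
    spec: SpectralEstimate,
    band: tuple[float, float] = DEFAULT_BAND,
    min_bins: int = 8,
) -> SpectralEstimate:
    """alpha from a degree-1 log10-log10 least-squares fit over the band.

    If the segment length cannot resolve the lower band edge, the edge is
    raised to 4 / segment length with a warning (a 2,500-tablet lower edge
    needs segments of at least 2,500 tablets). Zero-power bins are dropped
    with a warning.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    min_resolvable = 2.0 / spec.segment_length
    if f_lo < min_resolvable:
        f_lo = min_resolvable
        warnings.warn(
            f"band lower edge raised to {f_lo:.2e} (2 / segment length); "
            f"segments of {spec.segment_length} tablets cannot resolve the requested edge",
            stacklevel=2,
        )
    sel = (spec.f >= f_lo) & (spec.f <= f_hi)
    if np.any(spec.power[sel] <= 0):
        warnings.warn("dropping non-positive power bins in the fit band", stacklevel=2)
        sel &= spec.power > 0
    if sel.sum() < min_bins:
        raise ValueError(
            f"only {int(sel.sum())} usable frequency bins in band ({f_lo:.2e}, {f_hi:.2e}); "
            f"need >= {min_bins}"
        )
    lx = np.log10(spec.f[sel])
    ly = np.log10(spec.power[sel])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    slope = coef[0]
    n = lx.size
    resid = ly - A @ coef
    s2 = float(resid @ resid) / max(n - 2, 1)
    sxx = float(np.sum((lx - lx.mean()) ** 2))
    stderr = float(np.sqrt(s2 / sxx)) if sxx > 0 else float("nan")
    spec.alpha = float(-slope)
    spec.alpha_stderr = stderr
    spec.band = (float(f_lo), float(f_hi))
    return spec


def detect_flattening(
    spec: SpectralEstimate,
    f_threshold: float = 0.04,
    flat_tolerance: float = 0.15,
) -> SpectralEstimate:
    """Log-log slope above ``f_threshold`` with a sign classification.

    ``rising`` indicates the corrective-growth signature (a negative
    lag-1 thickness autocorrelation makes the spectrum increase with f),
    ``decaying`` a continuing 1/f fall-off, ``flat`` anything within
    ``flat_tolerance`` of zero slope.
    """
    sel = (spec.f > f_threshold) & (spec.power > 0)
    if sel.sum() < 4:
        raise ValueError(f"no usable frequency bins above {f_threshold}")
    lx = np.log10(spec.f[sel])
    ly = np.log10(spec.power[sel])
    slope = float(np.polyfit(lx, ly, 1)[0])
    if slope > flat_tolerance:
        cls = "rising"
    elif slope < -flat_tolerance:
        cls = "decaying"
    else:
        cls = "flat"
    spec.high_f_slope = slope
    spec.high_f_class = cls
    return spec
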