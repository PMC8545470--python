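"""1D pair-correlation analysis of layer stacking: peaks, broadening, order.

The pair-correlation function g(x) is the discretized probability density of
finding another interface at separation x from a given interface: all
pairwise separations within each transect are histogrammed with bin width
``bw`` and normalized by 1/(k*bw), k being the number of sampled pairs. For
a layered stack with mean spacing d, g shows peaks near n*d whose widths
encode the stacking statistics:

* crystal-like order: every peak equally sharp (sigma_n flat);
* ideal paracrystal (cumulative disorder): sigma_n = sigma_1 * sqrt(n),
  because the n-th spacing is a sum of n independent increments.

The broadening exponent beta from sigma_n = sigma_1 * n^beta classifies the
stack between those extremes. Translational order is considered lost at the
first peak whose envelope amplitude falls below a fraction r* (default 10%)
of the first peak's; that order times the mean spacing is the correlation
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .profile import ThicknessProfile, position_segments

__all__ = [
    "PairCorrelogram",
    "PeakFit",
    "ParacrystalAssessment",
    "pair_correlation",
    "fit_peaks",
    "broadening_curve",
    "correlation_length",
    "assess_paracrystal",
]


@dataclass
class PairCorrelogram:
    x: np.ndarray  # bin centers, nm
    g: np.ndarray  # 1/(k*bw)-normalized histogram of pair separations
    bw: float  # bin width, nm
    k: int  # number of sampled pairs (within the window)
    mean_spacing: float  # nm, median nearest-neighbor spacing of the input

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.g = np.asarray(self.g, dtype=float)


@dataclass
class PeakFit:
    """Per-order Gaussian components of the correlogram plus a flat baseline."""

    order: np.ndarray  # 1, 2, ... n
    mu: np.ndarray  # peak centers, nm
    sigma: np.ndarray  # peak SDs, nm
    height: np.ndarray  # amplitudes above baseline
    baseline: float
    residual: float  # RMS misfit
    converged: bool
    correlogram: PairCorrelogram

    def model(self, x: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(x, float), self.baseline)
        for m, s, h in zip(self.mu, self.sigma, self.height):
            out += h * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out

    def envelope_amplitudes(self) -> np.ndarray:
        """Oscillation amplitude of the fitted model at each peak.

        Half the peak-to-trough excursion of the fitted curve: the peak value
        minus the mean of the model at the midpoints to the neighboring
        peaks. For well-separated peaks this equals the Gaussian amplitude;
        for overlapping high-order peaks it measures the surviving
        oscillation of the pair-correlation envelope, which is what fades as
        translational order is lost.
        """
        n = self.mu.size
        amps = np.empty(n)
        for i in range(n):
            left_mid = self.mu[i] / 2.0 if i == 0 else 0.5 * (self.mu[i - 1] + self.mu[i])
            right_mid = (
                self.mu[i] + 0.5 * (self.mu[i] - left_mid) * 2.0
                if i == n - 1
                else 0.5 * (self.mu[i] + self.mu[i + 1])
            )
            peak = self.model(np.array([self.mu[i]]))[0]
            trough = 0.5 * (
                self.model(np.array([left_mid]))[0] + self.model(np.array([right_mid]))[0]
            )
            amps[i] = max(peak - trough, 0.0)
        return amps


@dataclass
class ParacrystalAssessment:
    sigma1_nm: float
    beta: float
    classification: str  # crystal-like | intermediate | ideal-paracrystal
    correlation_length_layers: int | None  # None = exceeds fitted window
    correlation_length_nm: float | None
    r_star: float
    mean_spacing_nm: float


# ---------------------------------------------------------------------------
# correlogram


def _as_position_segments(data) -> list[np.ndarray]:
    if isinstance(data, ThicknessProfile):
        return position_segments(data)
    if isinstance(data, np.ndarray):
        return [np.sort(np.asarray(data, dtype=float))]
    # iterable of arrays (e.g. several transects)
    segs = [np.sort(np.asarray(seg, dtype=float)) for seg in data]
    return segs


def pair_correlation(
    data,
    bw: float | None = None,
    x_max: float | None = None,
) -> PairCorrelogram:
    """Histogram of all intra-transect pairwise separations, 1/(k*bw)-normalized.

    ``data`` may be a :class:`ThicknessProfile` (positions are cumulative
    thickness sums; flagged layers split the transect), a single array of
    interface positions, or an iterable of such arrays (one per transect; no
    cross-transect pairs are formed). Defaults: ``bw`` = d/20 and ``x_max`` =
    30 d, with d the median nearest-neighbor spacing.
    """
    segs = [s for s in _as_position_segments(data) if s.size >= 2]
    if sum(s.size for s in segs) < 3:
        raise ValueError("need at least 3 interface positions")
    spacings = np.concatenate([np.diff(s) for s in segs])
    d = float(np.median(spacings))
    if bw is None:
        bw = d / 20.0
    if x_max is None:
        x_max = 30.0 * d
    if bw <= 0:
        raise ValueError("bw must be > 0")
    if bw >= d:
        raise ValueError(
            f"bin width {bw} nm does not resolve the mean spacing {d:.1f} nm; choose bw < spacing"
        )

    nbin = int(math.ceil(x_max / bw))
    counts = np.zeros(nbin)
    k = 0
    for s in segs:
        hi = np.searchsorted(s, s + x_max, side="right")
        for i in range(s.size - 1):
            sep = s[i + 1 : hi[i]] - s[i]
            if sep.size:
                idx = np.minimum((sep / bw).astype(int), nbin - 1)
                np.add.at(counts, idx, 1)
                k += sep.size
    if k == 0:
        raise ValueError("no pairs within x_max")
    g = counts / (k * bw)
    x = (np.arange(nbin) + 0.5) * bw
    return PairCorrelogram(x=x, g=g, bw=bw, k=k, mean_spacing=d)


# ---------------------------------------------------------------------------
# peak fitting


def _multi_gauss(x, *params):
    c = params[0]
    out = np.full_like(x, c)
    for j in range((len(params) - 1) // 3):
        h, m, s = params[1 + 3 * j : 4 + 3 * j]
        out = out + h * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def fit_peaks(corr: PairCorrelogram, n_max: int = 10) -> PeakFit:
    """Joint least-squares fit of a constant baseline plus n_max Gaussians.

    Initialized from the local maxima of the lightly smoothed correlogram at
    multiples of the mean spacing; the baseline starts at the tail level
    (asymptotic pair density). Falls back to a sequential per-peak fit if
    the joint optimization fails.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    d = corr.mean_spacing
    if corr.x[-1] < n_max * d:
        raise ValueError(
            f"correlogram window ({corr.x[-1]:.0f} nm) must cover n_max*d ({n_max * d:.0f} nm)"
        )
    x, g = corr.x, corr.g
    smooth = ndimage.gaussian_filter1d(g, 1.0)
    baseline0 = float(np.median(g[x > (n_max - 0.5) * d])) if np.any(x > (n_max - 0.5) * d) else float(
        np.median(g)
    )

    p0 = [baseline0]
    lo = [0.0]
    hi_b = [np.inf]
    sigma1_guess = None
    for n in range(1, n_max + 1):
        sel = (x > (n - 0.45) * d) & (x < (n + 0.45) * d)
        if not sel.any():
            raise ValueError("empty fit window; decrease n_max or increase x_max")
        xi, gi = x[sel], smooth[sel]
        mu0 = float(xi[np.argmax(gi)])
        h0 = max(float(gi.max() - baseline0), 1e-12)
        if sigma1_guess is None:
            # second moment above baseline around the first peak
            wgt = np.clip(gi - baseline0, 0, None)
            if wgt.sum() > 0:
                sigma1_guess = float(
                    math.sqrt(np.sum(wgt * (xi - mu0) ** 2) / np.sum(wgt))
                )
            sigma1_guess = max(sigma1_guess or corr.bw, corr.bw / 2.0)
        s0 = min(sigma1_guess * math.sqrt(n), 0.9 * d)
        p0 += [h0, mu0, s0]
        lo += [0.0, (n - 0.45) * d, corr.bw / 4.0]
        hi_b += [np.inf, (n + 0.45) * d, 1.2 * d]

    window = x <= (n_max + 0.6) * d
    converged = True
    try:
        popt, _ = curve_fit(
            _multi_gauss,
            x[window],
            g[window],
            p0=p0,
            bounds=(lo, hi_b),
            maxfev=40000,
        )
    except RuntimeError:
        converged = False
        popt = np.array(p0, dtype=float)

    baseline = float(popt[0])
    heights = popt[1::3].astype(float)
    mus = popt[2::3].astype(float)
    sigmas = popt[3::3].astype(float)
    order = np.argsort(mus)
    fitres = PeakFit(
        order=np.arange(1, n_max + 1),
        mu=mus[order],
        sigma=sigmas[order],
        height=heights[order],
        baseline=baseline,
        residual=float(
            np.sqrt(np.mean((_multi_gauss(x[window], *popt) - g[window]) ** 2))
        ),
        converged=converged,
        correlogram=corr,
    )
    if not converged:
        raise RuntimeError(
            "pair-correlation peak fit did not converge; partial fit attached"
        ) from None
    return fitres


# ---------------------------------------------------------------------------
# paracrystal assessment


def broadening_curve(
    fit: PeakFit,
    crystal_threshold: float = 0.15,
    paracrystal_threshold: float = 0.4,
) -> tuple[float, float, str]:
    """(sigma_1, beta, classification) from log-log regression of sigma_n vs n.

    beta = 0 for a crystal (resolution-limited, equally sharp peaks),
    beta = 1/2 for an ideal paracrystal (sigma_n = sigma_1 sqrt(n)).
    """
    if fit.order.size < 3:
        raise ValueError("need at least 3 fitted peaks for a broadening exponent")
    ln_n = np.log(fit.order.astype(float))
    ln_s = np.log(fit.sigma)
    beta, intercept = np.polyfit(ln_n, ln_s, 1)
    sigma1 = float(np.exp(intercept))
    if beta < crystal_threshold:
        cls = "crystal-like"
    elif beta > paracrystal_threshold:
        cls = "ideal-paracrystal"
    else:
        cls = "intermediate"
    return sigma1, float(beta), cls


def correlation_length(
    fit: PeakFit,
    r_star: float = 0.1,
    mean_spacing: float | None = None,
) -> tuple[int | None, float | None]:
    """First peak order whose envelope amplitude drops below r* of the first's.

    Returns (order, order * mean spacing in nm); (None, None) when the
    envelope survives to the end of the fitted window ("exceeds window").
    The first crossing wins; noisy re-entries above r* are ignored.
    """
    if mean_spacing is None:
        mean_spacing = fit.correlogram.mean_spacing
    amps = fit.envelope_amplitudes()
    if amps[0] <= 0:
        raise ValueError("degenerate fit: first peak has no amplitude")
    ratios = amps / amps[0]
    below = np.where(ratios < r_star)[0]
    if below.size == 0:
        return None, None
    n_loss = int(fit.order[below[0]])
    return n_loss, float(n_loss * mean_spacing)


def assess_paracrystal(
    fit: PeakFit,
    r_star: float = 0.1,
    crystal_threshold: float = 0.15,
    paracrystal_threshold: float = 0.4,
) -> ParacrystalAssessment:
    """Bundle broadening exponent, classification and correlation length."""
    sigma1, beta, cls = broadening_curve(fit, crystal_threshold, paracrystal_threshold)
    n_loss, nm_loss = correlation_length(fit, r_star)
    return ParacrystalAssessment(
        sigma1_nm=float(fit.sigma[0]),
        beta=beta,
        classification=cls,
        correlation_length_layers=n_loss,
        correlation_length_nm=nm_loss,
        r_star=r_star,
        mean_spacing_nm=fit.correlogram.mean_spacing,
    )
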