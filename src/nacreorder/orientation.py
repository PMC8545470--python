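"""Shared interface-orientation criterion.

The angular order of nacre interfaces is summarized by a single half-width:
the half-width at half maximum (HWHM), in degrees, of the distribution of
local interface tilt angles theta = arctan(du/dx) relative to the mean layer
plane. The generator calibrates its roughness amplitude against this
criterion and the Fourier-space estimator reports the same criterion, so the
two sides of every synthetic-recovery test measure one quantity.

For Gaussian slopes s ~ N(0, sigma_s), the tilt-angle density is
p(theta) = phi(tan theta / sigma_s) * sec^2(theta) / sigma_s, and the HWHM is
obtained numerically (for small widths it approaches 1.1774 * sigma_s in
radians, the Gaussian HWHM).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

_GAUSS_HWHM = np.sqrt(2.0 * np.log(2.0))  # 1.1774: HWHM of a unit Gaussian


def tilt_density(theta_rad: np.ndarray, sigma_s: float) -> np.ndarray:
    """Density of theta = arctan(s) for Gaussian slopes s ~ N(0, sigma_s)."""
    t = np.tan(theta_rad)
    return norm.pdf(t, scale=sigma_s) / np.cos(theta_rad) ** 2


def hwhm_deg_from_slope_sigma(sigma_s: float) -> float:
    """HWHM (degrees) of the tilt-angle distribution for slope SD sigma_s."""
    if sigma_s <= 0:
        return 0.0
    p0 = tilt_density(np.array(0.0), sigma_s)

    def f(theta):
        return tilt_density(np.array(theta), sigma_s) - 0.5 * p0

    # density is unimodal and -> 0 at 90 deg for the widths used here
    hi = np.pi / 2 - 1e-6
    if f(hi) > 0:
        raise ValueError(f"slope SD {sigma_s} too large for a HWHM criterion")
    return float(np.degrees(brentq(f, 0.0, hi)))


def slope_sigma_for_hwhm_deg(hwhm_deg: float) -> float:
    """Slope SD giving a requested tilt-angle HWHM (degrees); inverse map."""
    if hwhm_deg < 0 or hwhm_deg >= 90.0:
        raise ValueError("orientation half-width must lie in [0, 90) degrees")
    if hwhm_deg == 0:
        return 0.0
    target = float(hwhm_deg)

    def f(sig):
        return hwhm_deg_from_slope_sigma(sig) - target

    # bracket: HWHM(sigma) is increasing; sigma ~ tan(hwhm/1.1774) is close
    lo = 0.25 * np.tan(np.radians(target) / _GAUSS_HWHM)
    hi = 4.0 * np.tan(np.radians(target) / _GAUSS_HWHM)
    return float(brentq(f, lo, hi, xtol=1e-10))
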