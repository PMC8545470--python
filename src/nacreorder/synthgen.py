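"""Synthetic nacre: thickness profiles, interface fields, BSE-like micrographs.

The generator emulates the stochastic structure of nacre tablet stacking so
that every analysis stage can be exercised against known ground truth:

* tablet thickness w_N = clip(d_mean + e_N + c_N, floor), where

  - c_N is a stationary AR(1) "corrective" term, c_N = phi * c_{N-1} + eps_N
    with i.i.d. Gaussian innovations (SD ``sigma_local``). A negative phi
    reproduces the observed self-correcting growth: a tablet grown thick
    tends to be followed by a thin one.
  - e_N is a long-memory "environmental" modulation synthesized in the
    frequency domain with power spectral density proportional to
    f^-alpha_env, scaled to RMS ``sigma_env``. It reproduces the 1/f-type
    thickness fluctuations seen over tens to thousands of tablets.

* interfaces acquire lateral roughness: each interface i carries a
  transverse displacement field u_i(x) with u_{i+1} = a u_i + sqrt(1-a^2) v_i
  (a = ``roughness_attenuation``), where v_i is fresh Gaussian-smoothed noise
  of correlation length ``roughness_corr_length``. Amplitudes are calibrated
  so the tilt-angle distribution arctan(du/dx) has a requested half-width,
  the same criterion the Fourier estimator reports. This emulates bumps and
  valleys that are attenuated (carried over only partially) from one layer
  to the next.

* rendering draws each interlamellar sheath as a dark Gaussian-profile line
  on a bright tablet background (backscatter-SEM-like contrast), followed by
  Gaussian blur and additive Gaussian noise.

* screw-dislocation-like defects are inserted as terminating partial sheaths
  with local tablet thinning.

All randomness flows through integer seeds; identical specs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import fsolve
from scipy.stats import norm

from .orientation import slope_sigma_for_hwhm_deg
from .profile import ThicknessProfile

__all__ = [
    "GrowthSpec",
    "RenderSpec",
    "InterfaceField",
    "SyntheticSample",
    "make_thickness_profile",
    "make_interface_field",
    "render_micrograph",
    "make_synthetic_sample",
    "insert_dislocations",
    "growth_preset",
    "sample_preset",
    "PRESET_STAGE_STATS",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GrowthSpec:
    """Parameters of the stochastic tablet-stacking model (lengths in nm)."""

    n_layers: int
    mean_thickness: float = 340.0
    sigma_local: float = 95.0
    phi: float = -0.4
    sigma_env: float = 60.0
    alpha_env: float = 1.5
    floor: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_layers, (int, np.integer)) and self.n_layers >= 1):
            raise ValueError(f"n_layers must be a positive integer, got {self.n_layers!r}")
        for name in ("mean_thickness", "sigma_local", "sigma_env", "alpha_env", "floor", "phi"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.floor <= 0:
            raise ValueError(f"floor must be > 0, got {self.floor}")
        if self.mean_thickness <= self.floor:
            raise ValueError(
                f"mean_thickness ({self.mean_thickness}) must exceed floor ({self.floor})"
            )
        if self.sigma_local < 0 or self.sigma_env < 0:
            raise ValueError("sigma_local and sigma_env must be >= 0")
        if not (-1.0 < self.phi < 1.0):
            raise ValueError(f"phi must lie in (-1, 1), got {self.phi}")


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for BSE-like cross-sectional micrographs.

    Intensities are on a [0, 1] scale; ``gray_tablet - gray_sheath`` is the
    tablet/sheath contrast. ``noise_sd`` defaults to 10% of that contrast.
    """

    pixel_size: float = 3.0  # nm / px
    sheath_width: float = 15.0  # nm, FWHM-like width of the dark line
    gray_tablet: float = 0.80
    gray_sheath: float = 0.30
    blur_sd: float = 2.0  # px
    noise_sd: float = 0.05  # intensity units
    orientation_halfwidth: float = 5.0  # degrees, tilt-angle HWHM
    roughness_corr_length: float = 800.0  # nm, lateral correlation length
    roughness_attenuation: float = 0.0  # per-layer carry-over in [0, 1]
    image_width: int = 257  # px

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.gray_sheath >= self.gray_tablet:
            raise ValueError("gray_sheath must be below gray_tablet")
        if self.orientation_halfwidth < 0:
            raise ValueError("orientation_halfwidth must be >= 0")
        if self.orientation_halfwidth >= 90:
            raise ValueError("orientation_halfwidth must be < 90 degrees")
        if not (0.0 <= self.roughness_attenuation <= 1.0):
            raise ValueError("roughness_attenuation must lie in [0, 1]")
        if self.sheath_width <= 0:
            raise ValueError("sheath_width must be > 0")
        if self.image_width < 1:
            raise ValueError("image_width must be >= 1")
        if self.blur_sd < 0 or self.noise_sd < 0:
            raise ValueError("blur_sd and noise_sd must be >= 0")

    @property
    def contrast(self) -> float:
        return self.gray_tablet - self.gray_sheath


@dataclass
class InterfaceField:
    """Per-layer interface curves y_i(x): positions (nm) vs lateral column."""

    y: np.ndarray  # (n_interfaces, width) nm, strictly increasing along axis 0
    pixel_size: float  # nm / px (lateral sampling step of the columns)
    floor: float  # nm, minimum admissible spacing
    # partial sheaths from inserted dislocations: (layer, x0_col, direction)
    partials: list[tuple[int, int, int]] = field(default_factory=list)
    n_clipped: int = 0  # columns where non-crossing clipping engaged

    @property
    def n_interfaces(self) -> int:
        return self.y.shape[0]

    @property
    def width(self) -> int:
        return self.y.shape[1]

    def column_thickness(self, col: int) -> np.ndarray:
        return np.diff(self.y[:, col])


@dataclass
class SyntheticSample:
    """Rendered micrograph plus full per-column ground truth."""

    image: np.ndarray  # 2D float intensities in [0, 1]
    pixel_size: float  # nm / px
    truth_interfaces: np.ndarray  # (n_interfaces, width) nm per column
    truth_profile: ThicknessProfile  # thicknesses at the reference column
    truth_defects: list[tuple[float, float, str]]  # (x_nm, y_nm, view)
    reference_column: int
    field: InterfaceField
    growth: GrowthSpec | None
    render: RenderSpec
    render_seed: int

    @property
    def n_layers(self) -> int:
        return self.truth_interfaces.shape[0] - 1


# ---------------------------------------------------------------------------
# thickness profile


def _env_modulation(n: int, alpha: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean sequence with PSD ~ f^-alpha, scaled to exact sample RMS sigma.

    Synthesized by inverse real FFT of amplitudes proportional to f^(-alpha/2)
    with uniform random phases; the zero-frequency term is zero, so the
    sequence is exactly zero-mean.
    """
    if sigma == 0.0 or n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    e = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(e**2))
    if rms == 0.0:
        return np.zeros(n)
    return e * (sigma / rms)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample: c_N = phi c_{N-1} + eps_N, eps ~ N(0, sigma)."""
    if sigma == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma, size=n)
    c = np.empty(n)
    c[0] = rng.normal(0.0, sigma / math.sqrt(1.0 - phi**2))
    for i in range(1, n):
        c[i] = phi * c[i - 1] + eps[i]
    return c


def make_thickness_profile(spec: GrowthSpec) -> ThicknessProfile:
    """Draw a tablet-thickness profile from the stacking model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    e = _env_modulation(spec.n_layers, spec.alpha_env, spec.sigma_env, rng)
    c = _ar1(spec.n_layers, spec.phi, spec.sigma_local, rng)
    w = spec.mean_thickness + e + c
    np.clip(w, spec.floor, None, out=w)
    return ThicknessProfile(w)


# ---------------------------------------------------------------------------
# clip-aware preset calibration


def _clipped_moments(mu: float, sigma: float, floor: float) -> tuple[float, float]:
    """Mean and SD of max(X, floor) for X ~ N(mu, sigma)."""
    if sigma == 0:
        m = max(mu, floor)
        return m, 0.0
    z = (floor - mu) / sigma
    Phi = norm.cdf(z)
    phi = norm.pdf(z)
    m = mu + sigma * (z * Phi + phi)
    ex2 = (
        floor**2 * Phi
        + mu**2 * (1.0 - Phi)
        + 2.0 * mu * sigma * phi
        + sigma**2 * ((1.0 - Phi) + z * phi)
    )
    var = max(ex2 - m * m, 0.0)
    return m, math.sqrt(var)


def _solve_preclip(target_mean: float, target_sd: float, floor: float) -> tuple[float, float]:
    """Pre-clip (mu, sigma) whose floor-clipped Gaussian has the target moments.

    The thickness marginal before clipping is Gaussian (sum of the Gaussian
    environmental and AR components), so presets can state realized
    statistics and compensate the floor clip exactly.
    """

    def eqs(p):
        m, s = _clipped_moments(p[0], p[1], floor)
        return [m - target_mean, s - target_sd]

    sol = fsolve(eqs, x0=[target_mean, target_sd], full_output=False, xtol=1e-12)
    mu, sigma = float(sol[0]), float(sol[1])
    return mu, sigma


#: Stage statistics (mean, SD, orientation half-width) the presets target.
PRESET_STAGE_STATS = {
    "early": {"mean": 500.0, "sd": 300.0, "halfwidth_deg": 15.0},
    "mature": {"mean": 340.0, "sd": 120.0, "halfwidth_deg": 5.0},
}

_ENV_VARIANCE_FRACTION = 0.25  # share of thickness variance in the f^-alpha term


def _growth_from_marginal(
    n_layers: int,
    mean: float,
    sd: float,
    *,
    phi: float = -0.4,
    alpha_env: float = 1.5,
    floor: float = 50.0,
    seed: int = 0,
) -> GrowthSpec:
    mu0, sig0 = _solve_preclip(mean, sd, floor)
    var_env = _ENV_VARIANCE_FRACTION * sig0**2
    var_ar = sig0**2 - var_env
    sigma_local = math.sqrt(var_ar * (1.0 - phi**2))
    return GrowthSpec(
        n_layers=n_layers,
        mean_thickness=mu0,
        sigma_local=sigma_local,
        phi=phi,
        sigma_env=math.sqrt(var_env),
        alpha_env=alpha_env,
        floor=floor,
        seed=seed,
    )


def growth_preset(name: str, n_layers: int = 1000, seed: int = 0) -> GrowthSpec:
    """Named growth stages with the observed stage statistics.

    ``early`` targets 500 +/- 300 nm tablets, ``mature`` 340 +/- 120 nm;
    ``full-pearl`` is the mature stage at the full 2,615-layer count.
    """
    if name == "full-pearl":
        stats = PRESET_STAGE_STATS["mature"]
        return _growth_from_marginal(2615, stats["mean"], stats["sd"], seed=seed)
    if name not in PRESET_STAGE_STATS:
        raise ValueError(f"unknown preset {name!r}; choose early, mature or full-pearl")
    stats = PRESET_STAGE_STATS[name]
    return _growth_from_marginal(n_layers, stats["mean"], stats["sd"], seed=seed)


# ---------------------------------------------------------------------------
# interface field


def _gaussian_kernel(sigma_px: float) -> np.ndarray:
    half = max(int(math.ceil(4.0 * sigma_px)), 1)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / np.sqrt(np.sum(k**2))  # unit output variance for white input


def _smooth_noise(width: int, kernel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pad = kernel.size // 2
    white = rng.normal(size=width + 2 * pad)
    return np.convolve(white, kernel, mode="valid")


def _unit_slope_sd(kernel: np.ndarray, pixel_size: float) -> float:
    """Slope SD (per nm) of a unit-variance field built from this kernel."""
    dk = np.convolve(kernel, [0.5, 0.0, -0.5], mode="full")
    return float(np.sqrt(np.sum(dk**2)) / pixel_size)


def make_interface_field(
    profile: ThicknessProfile,
    render: RenderSpec,
    seed: int = 0,
    margin_nm: float | None = None,
    floor_nm: float = 50.0,
) -> InterfaceField:
    """Stack interfaces cumulatively and add correlated lateral roughness.

    Interface i (i = 0..n_layers) sits at the cumulative thickness sum plus a
    transverse displacement field u_i(x); adjacent displacement fields share
    a fraction ``roughness_attenuation`` of their structure. Displacements
    are clipped where they would push the local spacing below the growth
    floor, so curves never cross.
    """
    render.validate()
    w = profile.thickness_nm
    if not np.all(np.isfinite(w)):
        raise ValueError("profile thicknesses must be finite")
    rng = np.random.default_rng(seed)
    width = render.image_width
    if margin_nm is None:
        margin_nm = 3.0 * render.sheath_width + 5.0 * render.blur_sd * render.pixel_size + 15.0

    base = margin_nm + np.concatenate([[0.0], np.cumsum(w)])
    n_if = base.size
    y = np.tile(base[:, None], (1, width))

    sigma_s = slope_sigma_for_hwhm_deg(render.orientation_halfwidth)
    if sigma_s > 0 and width >= 3:
        # kernel sigma from the requested correlation length: the smoothed
        # white noise has Gaussian autocorrelation with length sqrt(2)*sigma_k
        sigma_k_px = render.roughness_corr_length / render.pixel_size / math.sqrt(2.0)
        kernel = _gaussian_kernel(sigma_k_px)
        sigma_u = sigma_s / _unit_slope_sd(kernel, render.pixel_size)
        a = render.roughness_attenuation
        u = sigma_u * _smooth_noise(width, kernel, rng)
        y[0] += u
        for i in range(1, n_if):
            v = sigma_u * _smooth_noise(width, kernel, rng)
            u = a * u + math.sqrt(1.0 - a * a) * v
            y[i] += u

    # anchor the whole field so displacement cannot push curves off the top
    y += margin_nm - y.min()

    # enforce non-crossing: local spacing never below the admissible floor
    # (the growth floor, or the thinnest true tablet if that is thinner)
    gap = float(min(floor_nm, w.min())) if w.size else 0.0
    n_clipped = 0
    for i in range(1, n_if):
        low = y[i - 1] + gap
        mask = y[i] < low
        if mask.any():
            n_clipped += int(mask.sum())
            y[i] = np.where(mask, low, y[i])

    return InterfaceField(y=y, pixel_size=render.pixel_size, floor=gap, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# rendering


def render_micrograph(
    field: InterfaceField,
    render: RenderSpec,
    seed: int = 0,
    growth: GrowthSpec | None = None,
    truth_defects: list[tuple[float, float, str]] | None = None,
) -> SyntheticSample:
    """Rasterize interface curves into a BSE-like grayscale micrograph.

    Sheaths are dark Gaussian-profile lines centered exactly on the interface
    curves: with no blur and no noise, column-wise intensity minima sit at
    the sheath centerlines. Partial sheaths (dislocations) recorded on the
    field are drawn over their half-range only.
    """
    render.validate()
    px = render.pixel_size
    y = field.y
    margin = 3.0 * render.sheath_width + 5.0 * render.blur_sd * px + 15.0
    height = int(math.ceil((y.max() + margin) / px))
    width = field.width
    if y.min() < 0:
        raise ValueError("interface positions must be non-negative")

    sigma_sheath_px = (render.sheath_width / 2.0) / px
    k_half = max(int(math.ceil(4.0 * sigma_sheath_px)), 2)
    cols = np.arange(width)
    depth = np.zeros((height, width), dtype=np.float32)

    partial_by_layer = {}
    for layer, x0, direction in field.partials:
        partial_by_layer.setdefault(layer, []).append((x0, direction))

    def splat(curve_px: np.ndarray, col_mask: np.ndarray | None = None) -> None:
        r0 = np.round(curve_px).astype(int)
        use_cols = cols if col_mask is None else cols[col_mask]
        if use_cols.size == 0:
            return
        r0u = r0[use_cols]
        cu = curve_px[use_cols]
        for dk in range(-k_half, k_half + 1):
            rows = r0u + dk
            valid = (rows >= 0) & (rows < height)
            if not valid.any():
                continue
            dd = rows[valid] - cu[valid]
            depth[rows[valid], use_cols[valid]] += np.exp(
                -0.5 * (dd / sigma_sheath_px) ** 2
            ).astype(np.float32)

    for i in range(field.n_interfaces):
        splat(y[i] / px)

    # terminating partial sheaths at the midline of their (thinned) host layer
    for layer, entries in partial_by_layer.items():
        mid = 0.5 * (y[layer] + y[layer + 1]) / px
        for x0, direction in entries:
            mask = cols >= x0 if direction > 0 else cols <= x0
            splat(mid, mask)

    np.clip(depth, 0.0, 1.0, out=depth)
    image = (render.gray_tablet - render.contrast * depth).astype(np.float32)
    del depth
    if render.blur_sd > 0:
        image = ndimage.gaussian_filter(image, render.blur_sd)
    if render.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(image.shape, dtype=np.float32)
        image += render.noise_sd * noise
        del noise
    np.clip(image, 0.0, 1.0, out=image)

    ref = width // 2
    truth_profile = ThicknessProfile(np.diff(y[:, ref]))
    return SyntheticSample(
        image=image.astype(np.float32),
        pixel_size=px,
        truth_interfaces=y,
        truth_profile=truth_profile,
        truth_defects=list(truth_defects or []),
        reference_column=ref,
        field=field,
        growth=growth,
        render=render,
        render_seed=seed,
    )


def make_synthetic_sample(
    growth: GrowthSpec,
    render: RenderSpec,
    seed: int | None = None,
) -> SyntheticSample:
    """Profile -> interface field -> rendered micrograph, one seed stream."""
    base = growth.seed if seed is None else seed
    profile = make_thickness_profile(replace(growth, seed=base))
    field = make_interface_field(profile, render, seed=base + 1, floor_nm=growth.floor)
    return render_micrograph(field, render, seed=base + 2, growth=growth)


def sample_preset(
    name: str,
    n_layers: int = 500,
    seed: int = 0,
    image_width: int | None = None,
) -> SyntheticSample:
    """Rendered early/mature/full-pearl scenes with calibrated column statistics.

    The thickness measured along an image column is the stacking thickness
    plus the difference of adjacent interface displacements; the preset
    splits the stage variance between the two so that the *measured*
    column-wise statistics match the stage values (e.g. 340 +/- 120 nm
    mature). The stacking profile alone therefore carries less variance than
    the stage SD.
    """
    if name == "full-pearl":
        stage = PRESET_STAGE_STATS["mature"]
        n_layers = 2615
    elif name in PRESET_STAGE_STATS:
        stage = PRESET_STAGE_STATS[name]
    else:
        raise ValueError(f"unknown preset {name!r}; choose early, mature or full-pearl")

    hw = stage["halfwidth_deg"]
    sigma_s = slope_sigma_for_hwhm_deg(hw)
    # The stage thickness variance is split evenly-ish between stacking
    # disorder (sigma_w^2) and adjacent-interface displacement differences
    # (2 sigma_u^2 with fully independent per-layer roughness, a = 0), so
    # that a column-wise measurement sees the stage SD. Independent
    # roughness fields per layer are essential for the Fourier angular
    # measurement: partially correlated tilt fields diffract with a
    # *narrowed* azimuthal spread (the ring sees the coherently averaged
    # tilt), while a = 0 leaves the ring second moment unbiased and gives
    # every layer an independent tilt sample.
    sigma_w = 85.0 if name in ("mature", "full-pearl") else 212.0
    atten = 0.0
    var_w = min(sigma_w**2, stage["sd"] ** 2)
    var_rel = max(stage["sd"] ** 2 - var_w, 0.0)
    sigma_u = math.sqrt(var_rel / 2.0)
    # correlation length from the calibrated slope SD of the tilt field
    corr_len = sigma_u / sigma_s if sigma_s > 0 else 1000.0

    render = RenderSpec(
        orientation_halfwidth=hw,
        roughness_corr_length=corr_len,
        roughness_attenuation=atten,
        image_width=image_width if image_width is not None else (65 if name == "full-pearl" else 257),
    )
    growth = _growth_from_marginal(n_layers, stage["mean"], math.sqrt(var_w), seed=seed)
    return make_synthetic_sample(growth, render, seed=seed)


# ---------------------------------------------------------------------------
# dislocations


def insert_dislocations(
    sample: SyntheticSample,
    density: float,
    thinning_fraction: float = 0.28,
    decay_length: float = 500.0,
    mode: str = "exact",
    seed: int = 0,
) -> SyntheticSample:
    """Insert terminating partial sheaths with local tablet thinning.

    ``density`` is a defect areal density in m^-2 over the rendered field.
    In ``exact`` mode the number inserted is round(density * area); in
    ``poisson`` mode it is Poisson with that mean. Each defect thins its host
    tablet by ``thinning_fraction`` at the defect, decaying laterally with
    Gaussian scale ``decay_length`` (nm), and adds a partial extra sheath at
    the host midline on one side of the defect.
    """
    if density < 0:
        raise ValueError(f"defect density must be >= 0, got {density}")
    if not (0.0 <= thinning_fraction < 1.0):
        raise ValueError("thinning_fraction must lie in [0, 1)")
    field = sample.field
    px = sample.pixel_size
    height_nm = sample.image.shape[0] * px
    width_nm = field.width * px
    area_m2 = (height_nm * 1e-9) * (width_nm * 1e-9)
    rng = np.random.default_rng(seed)
    if mode == "exact":
        count = int(round(density * area_m2))
    elif mode == "poisson":
        count = int(rng.poisson(density * area_m2))
    else:
        raise ValueError(f"mode must be 'exact' or 'poisson', got {mode!r}")
    if count == 0:
        return sample

    y = field.y.copy()
    partials = list(field.partials)
    defects = list(sample.truth_defects)
    n_layers = y.shape[0] - 1
    x_nm = np.arange(field.width) * px
    for _ in range(count):
        layer = int(rng.integers(1, max(n_layers - 1, 2)))
        x0 = int(rng.integers(0, field.width))
        direction = 1 if rng.random() < 0.5 else -1
        envelope = np.exp(-0.5 * ((x_nm - x_nm[x0]) / decay_length) ** 2)
        w_local = y[layer + 1] - y[layer]
        y[layer + 1] = y[layer + 1] - w_local * thinning_fraction * envelope
        partials.append((layer, x0, direction))
        y_mid = 0.5 * (y[layer] + y[layer + 1])[x0]
        defects.append((float(x_nm[x0]), float(y_mid), "cross-section"))

    new_field = InterfaceField(
        y=y,
        pixel_size=field.pixel_size,
        floor=field.floor,
        partials=partials,
        n_clipped=field.n_clipped,
    )
    return render_micrograph(
        new_field,
        sample.render,
        seed=sample.render_seed,
        growth=sample.growth,
        truth_defects=defects,
    )
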