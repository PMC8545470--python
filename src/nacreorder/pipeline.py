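"""End-to-end orchestration: simulate or load, detect, analyze, report.

A :class:`PipelineConfig` fully determines a run (it round-trips through
YAML, and the report embeds the exact config used plus the package version
and seed, so any report can be regenerated). Stages:

1. input: synthetic preset, micrograph, or pre-extracted thickness profile;
2. detect: transect extraction, sheath minima, merged-layer flagging;
3. growthstats: stage summaries, adjacent-deviation correlation, growth rate;
4. paircorr: pair correlation, peak fit, paracrystal assessment;
5. spectral: segment-averaged PSD, 1/f exponent, high-frequency slope;
6. morpho: angular order (image inputs only) and defect density (when
   defect centers are available).

Image-dependent fields are reported as ``"not computed"`` for profile-only
inputs rather than silently omitted.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml

from . import detect, growthstats, io, morpho, paircorr, spectral, synthgen
from .profile import ThicknessProfile

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("nacreorder")

NOT_COMPUTED = "not computed"


@dataclass
class PipelineConfig:
    # input: exactly one of preset / image / profile
    preset: str | None = None  # early | mature | full-pearl
    image: str | None = None
    profile: str | None = None
    pixel_size_nm: float | None = None
    n_layers: int = 500
    image_width: int = 257
    seed: int = 0
    # detection
    n_transects: int = 1
    smoothing_sd: float | None = None
    min_prominence: float | None = None
    merged_tau: float = 1.8
    # analysis
    stage_window: int = 200  # layers per early/mature stage summary
    pc_n_max: int = 10
    psd_segments: int = 10
    psd_band: tuple[float, float] = spectral.DEFAULT_BAND
    days: float | None = None  # pearl lifetime for the growth rate
    # output
    out_dir: str | None = None

    def validate(self) -> None:
        chosen = [x for x in (self.preset, self.image, self.profile) if x]
        if len(chosen) != 1:
            raise ValueError("config must set exactly one of preset/image/profile")
        if self.image and not self.pixel_size_nm:
            # sidecar may still provide it; checked at load time
            pass


def save_config(config: PipelineConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["psd_band"] = list(d["psd_band"])
    Path(path).write_text(yaml.safe_dump(d))


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "psd_band" in d and d["psd_band"] is not None:
        d["psd_band"] = tuple(d["psd_band"])
    return PipelineConfig(**d)


def _profile_analyses(profile: ThicknessProfile, config: PipelineConfig) -> dict:
    out: dict = {}
    n = len(profile)

    # stage summaries: first and last stage_window layers (skipping is
    # pointless below 2 windows)
    win = min(config.stage_window, max(n // 2, 1))
    stages = growthstats.stage_statistics(
        profile, [(1, win), (max(n - win + 1, 1), n)], labels=["first", "last"]
    )
    out["stage_statistics"] = [dataclasses.asdict(s) for s in stages]
    ok = profile.ok_thickness
    out["mean_thickness_nm"] = float(ok.mean())
    out["sd_thickness_nm"] = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    out["n_layers"] = int(n)
    out["n_excluded"] = int(n - ok.size)

    try:
        devs = growthstats.rolling_deviation(profile)
        out["adjacent_correlation"] = dataclasses.asdict(
            growthstats.adjacent_correlation(devs)
        )
    except ValueError as exc:
        out["adjacent_correlation"] = str(exc)
    try:
        out["detrended_lag1_autocorrelation"] = growthstats.detrended_lag1_autocorrelation(
            profile
        )
    except ValueError:
        out["detrended_lag1_autocorrelation"] = NOT_COMPUTED

    if config.days:
        out["growth_rate"] = dataclasses.asdict(
            growthstats.growth_rate(n, config.days, out["mean_thickness_nm"])
        )

    try:
        corr = paircorr.pair_correlation(profile)
        fit = paircorr.fit_peaks(corr, n_max=config.pc_n_max)
        assess = paircorr.assess_paracrystal(fit)
        out["paracrystal"] = dataclasses.asdict(assess)
        out["pair_correlation"] = {
            "bw_nm": corr.bw,
            "k_pairs": corr.k,
            "mean_spacing_nm": corr.mean_spacing,
            "first_peak_nm": float(fit.mu[0]),
        }
    except (ValueError, RuntimeError) as exc:
        out["paracrystal"] = f"failed: {exc}"

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # short profiles cannot resolve the fit band with the canonical
            # segment count: keep segments at least ~250 tablets long
            n_seg = max(min(config.psd_segments, len(profile) // 250), 1)
            est = spectral.psd(profile, n_segments=n_seg)
            est = spectral.fit_powerlaw(est, band=config.psd_band)
            est = spectral.detect_flattening(est)
        out["spectral"] = {
            "alpha": est.alpha,
            "alpha_stderr": est.alpha_stderr,
            "band": list(est.band),
            "n_segments": est.n_segments,
            "high_f_slope": est.high_f_slope,
            "high_f_class": est.high_f_class,
        }
    except ValueError as exc:
        out["spectral"] = f"failed: {exc}"
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages; returns the report dict (units embedded).

    Deterministic given (config, seed). Intermediate CSVs and the report are
    written to ``config.out_dir`` when set.
    """
    config.validate()
    try:
        version = metadata.version("nacreorder")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    report: dict = {
        "config": dataclasses.asdict(config),
        "package_version": version,
        "units": {
            "length": "nm",
            "angle": "degrees",
            "defect_density": "m^-2",
            "frequency": "cycles/tablet",
        },
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    image = None
    pixel = config.pixel_size_nm
    sample = None
    if config.preset:
        log.info("stage=simulate preset=%s n_layers=%d seed=%d", config.preset, config.n_layers, config.seed)
        sample = synthgen.sample_preset(
            config.preset,
            n_layers=config.n_layers,
            seed=config.seed,
            image_width=config.image_width,
        )
        image, pixel = sample.image, sample.pixel_size
        if out_dir:
            io.write_image(image, out_dir / "synthetic.tif", pixel)
            io.write_profile_csv(sample.truth_profile, out_dir / "truth_profile.csv")
    elif config.image:
        log.info("stage=load image=%s", config.image)
        image, pixel = io.read_image(config.image, config.pixel_size_nm)

    if image is not None:
        log.info("stage=detect n_transects=%d", config.n_transects)
        tr = detect.extract_transect(image, pixel)
        det = detect.detect_sheaths(
            tr, smoothing_sd=config.smoothing_sd, min_prominence=config.min_prominence
        )
        if len(det) < 2:
            raise RuntimeError("stage detect failed: fewer than 2 interfaces found")
        profile = detect.flag_merged_layers(
            detect.thickness_from_interfaces(det), tau=config.merged_tau
        )
        if out_dir:
            io.write_interfaces_csv(det, out_dir / "interfaces.csv")
            io.write_profile_csv(profile, out_dir / "profile.csv")
        report["detection"] = {
            "n_interfaces": len(det),
            "n_layers": len(profile),
            "transect_direction_deg": tr.direction_deg,
        }
    else:
        profile = io.read_profile_csv(config.profile)
        report["detection"] = NOT_COMPUTED

    log.info("stage=analyze n_layers=%d", len(profile))
    report.update(_profile_analyses(profile, config))

    if image is not None:
        log.info("stage=morpho")
        try:
            ang = morpho.angular_spread(image, pixel)
            report["angular"] = {
                "half_width_deg": ang.half_width_deg,
                "center_deg": ang.center_deg,
                "ring_spacing_nm": 1.0 / ang.ring_frequency,
                "criterion": ang.criterion,
            }
        except ValueError as exc:
            report["angular"] = f"failed: {exc}"
    else:
        report["angular"] = NOT_COMPUTED

    if sample is not None and sample.truth_defects:
        h_m = image.shape[0] * pixel * 1e-9
        w_m = image.shape[1] * pixel * 1e-9
        dm = morpho.DefectMap(
            x_m=np.array([d[0] for d in sample.truth_defects]) * 1e-9,
            y_m=np.array([d[1] for d in sample.truth_defects]) * 1e-9,
            area_m2=h_m * w_m,
        )
        report["defects"] = dataclasses.asdict(morpho.defect_density(dm))
    else:
        report["defects"] = NOT_COMPUTED

    if out_dir:
        io.write_report_json(report, out_dir / "report.json")
        save_config(config, out_dir / "config.yaml")
    return report
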