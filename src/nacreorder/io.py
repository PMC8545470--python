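"""File I/O: profiles and interface tables (CSV), images (TIFF/PNG), reports.

Conventions: lengths in nm, layer indices 1-based and chronological
(pearl center -> edge), CSV files UTF-8 with a header row. Images are
grayscale 8/16-bit TIFF or PNG; the pixel size travels in a JSON sidecar
(``<image>.pixelsize.json``) or as an explicit argument.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detect import InterfaceSet
from .profile import VALID_FLAGS, ThicknessProfile

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "read_image",
    "write_image",
    "write_interfaces_csv",
    "write_report_json",
    "read_defects_csv",
]

PROFILE_COLUMNS = ["layer_index", "thickness_nm", "flag"]


def write_profile_csv(profile: ThicknessProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "layer_index": profile.layer_index,
            "thickness_nm": profile.thickness_nm,
            "flag": profile.flags,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path: str | Path) -> ThicknessProfile:
    """Read (layer_index, thickness_nm, flag) with strict validation."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: line 1: missing required column(s) {missing}; "
            f"expected header {PROFILE_COLUMNS}"
        )
    bad = ~df["flag"].isin(VALID_FLAGS)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: unknown flag value(s) at line(s) {rows}")
    w = df["thickness_nm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)):
        rows = (df.index[~np.isfinite(w)] + 2).tolist()[:5]
        raise ValueError(f"{path}: non-finite thickness at line(s) {rows}")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["layer_index"].to_numpy(), expected):
        raise ValueError(f"{path}: layer_index must be 1..{len(df)} in order")
    return ThicknessProfile(w, df["flag"].to_numpy(dtype=object))


def write_interfaces_csv(
    interfaces: InterfaceSet, path: str | Path, transect_id: int = 0
) -> None:
    pd.DataFrame(
        {
            "transect_id": transect_id,
            "interface_index": np.arange(1, len(interfaces) + 1),
            "position_nm": interfaces.positions,
            "prominence": interfaces.prominence,
        }
    ).to_csv(path, index=False)


def write_image(
    image: np.ndarray, path: str | Path, pixel_size_nm: float | None = None
) -> None:
    """Write grayscale image; [0, 1] floats are scaled to 16-bit for TIFF,
    8-bit for PNG. A pixel-size sidecar JSON is written when provided."""
    path = Path(path)
    img = np.asarray(image)
    if img.dtype.kind == "f":
        scaled = np.clip(img, 0.0, 1.0)
        if path.suffix.lower() in (".tif", ".tiff"):
            img = (scaled * 65535.0 + 0.5).astype(np.uint16)
        else:
            img = (scaled * 255.0 + 0.5).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    if pixel_size_nm is not None:
        sidecar = path.with_suffix(path.suffix + ".pixelsize.json")
        sidecar.write_text(json.dumps({"pixel_size_nm": pixel_size_nm}))


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> tuple[np.ndarray, float]:
    """Read a grayscale image as float in [0, 1] plus its pixel size (nm).

    The pixel size comes from the argument or from the sidecar JSON written
    by :func:`write_image`.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:  # collapse an RGB(A) read of a grayscale image
        img = img[..., 0]
    if img.dtype.kind in "ui":
        img = img.astype(np.float64) / np.iinfo(img.dtype).max
    else:
        img = img.astype(np.float64)
    if pixel_size_nm is None:
        sidecar = path.with_suffix(path.suffix + ".pixelsize.json")
        if not sidecar.exists():
            raise ValueError(
                f"pixel size unknown for {path}: pass pixel_size_nm or provide {sidecar.name}"
            )
        pixel_size_nm = float(json.loads(sidecar.read_text())["pixel_size_nm"])
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    return img, pixel_size_nm


def read_defects_csv(path: str | Path) -> pd.DataFrame:
    """Defect centers: columns (x_m, y_m, view)."""
    df = pd.read_csv(path)
    for c in ("x_m", "y_m"):
        if c not in df.columns:
            raise ValueError(f"{path}: line 1: missing required column {c!r}")
    if "view" not in df.columns:
        df["view"] = "cross-section"
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, allow_nan=True))
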