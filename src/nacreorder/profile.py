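"""Ordered tablet-thickness profiles along the nacre growth direction.

A :class:`ThicknessProfile` is the central in-memory container shared by the
generator and by every analysis stage: a chronological sequence of tablet
thicknesses (nm), indexed 1-based from the first-deposited layer (pearl
center) outward, with a per-layer flag that marks layers excluded from
downstream statistics (e.g. apparent double-thickness from a missed
interlamellar sheath).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed per-layer flags.
FLAG_OK = "ok"
FLAG_MERGED = "merged_excluded"
VALID_FLAGS = (FLAG_OK, FLAG_MERGED)


@dataclass
class ThicknessProfile:
    """Tablet thicknesses w_N (nm) in chronological (growth) order."""

    thickness_nm: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thickness_nm = np.asarray(self.thickness_nm, dtype=float)
        if self.thickness_nm.ndim != 1:
            raise ValueError("thickness_nm must be one-dimensional")
        if self.flags is None:
            self.flags = np.full(self.thickness_nm.shape, FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.thickness_nm.shape:
                raise ValueError("flags must match thickness_nm in length")
            bad = set(self.flags) - set(VALID_FLAGS)
            if bad:
                raise ValueError(f"unknown flags: {sorted(bad)!r}")

    def __len__(self) -> int:
        return self.thickness_nm.size

    @property
    def layer_index(self) -> np.ndarray:
        """1-based chronological layer indices (center -> edge)."""
        return np.arange(1, len(self) + 1)

    @property
    def ok_mask(self) -> np.ndarray:
        return self.flags == FLAG_OK

    @property
    def ok_thickness(self) -> np.ndarray:
        return self.thickness_nm[self.ok_mask]

    def positions(self, origin: float = 0.0) -> np.ndarray:
        """Interface positions (nm): origin plus the cumulative thickness sum.

        Returns ``len(self) + 1`` strictly increasing positions; the Nth
        tablet spans ``positions[N-1] .. positions[N]``.
        """
        return origin + np.concatenate([[0.0], np.cumsum(self.thickness_nm)])

    def segments(self) -> list[np.ndarray]:
        """Runs of consecutive unflagged thicknesses.

        Flagged layers split the profile: no pair statistic may straddle a
        flagged (excluded) layer.
        """
        out: list[np.ndarray] = []
        start = None
        for i, ok in enumerate(self.ok_mask):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                out.append(self.thickness_nm[start:i])
                start = None
        if start is not None:
            out.append(self.thickness_nm[start:])
        return out

    def copy(self) -> "ThicknessProfile":
        return ThicknessProfile(self.thickness_nm.copy(), self.flags.copy())


def position_segments(profile: ThicknessProfile, origin: float = 0.0) -> list[np.ndarray]:
    """Interface-position runs bounded by unflagged layers.

    Each returned array holds the interface positions delimiting one
    contiguous run of unflagged tablets (length = run length + 1).
    """
    pos = profile.positions(origin)
    out: list[np.ndarray] = []
    start = None
    ok = profile.ok_mask
    for i in range(len(profile)):
        if ok[i] and start is None:
            start = i
        elif not ok[i] and start is not None:
            out.append(pos[start : i + 1])
            start = None
    if start is not None:
        out.append(pos[start : len(profile) + 1])
    return out
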