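"""White/dark reflectance calibration and spectral band trimming.

Line-scan cameras drift with lamp output and sensor temperature, so raw
intensity ``Io`` is converted to reflectance against a white reference
``Iw`` (standard ~100% reflectance tile) and a dark reference ``Id``
(lens capped, lamp off)::

    Ic = (Io - Id) / (Iw - Id)

References may be full cubes or pre-reduced per-band scan-line profiles;
full reference cubes are averaged over the scan (y) axis by default, which
yields one response profile per (sensor column, band) — the standard
practice for push-broom instruments. Reflectance is deliberately not
clipped to [0, 1]: specular pixels can exceed the white tile.

The spectral extremes of InGaAs/VNIR sensors are noisy, so bands outside a
wavelength window (default 655-1642 nm) are trimmed before analysis; a
fraction-based mode (drop ``ceil(f*L)`` bands per end) is also available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .envi import Hypercube

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSet",
    "BandWindow",
    "calibrate",
    "trim_bands",
    "trim_bands_fraction",
    "DEFAULT_TRIM_LO_NM",
    "DEFAULT_TRIM_HI_NM",
]

DEFAULT_TRIM_LO_NM = 655.0
DEFAULT_TRIM_HI_NM = 1642.0


@dataclass
class ReferenceSet:
    """White (Iw) and dark (Id) reference cubes for one acquisition setup."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        if self.white.n_bands != self.dark.n_bands:
            raise ValueError(
                f"white has {self.white.n_bands} bands but dark has {self.dark.n_bands}"
            )
        w = self.white.data.mean(axis=(0, 1))
        d = self.dark.data.mean(axis=(0, 1))
        if np.any(w <= d):
            raise ValueError(
                "white reference is not brighter than dark reference in every band; "
                "references are swapped or invalid"
            )

    def profiles(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-(x, band) reference profiles, averaged over the scan axis."""
        return (
            self.white.data.mean(axis=0, dtype=float),
            self.dark.data.mean(axis=0, dtype=float),
        )


@dataclass
class BandWindow:
    """Contiguous retained wavelength window after trimming."""

    lo_nm: float
    hi_nm: float
    retained_indices: np.ndarray  # 0-based band indices into the untrimmed cube

    def __post_init__(self) -> None:
        if self.lo_nm >= self.hi_nm:
            raise ValueError(f"lo_nm {self.lo_nm} must be < hi_nm {self.hi_nm}")
        idx = np.asarray(self.retained_indices)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError("retained_indices must be contiguous")
        self.retained_indices = idx

    @property
    def n_retained(self) -> int:
        return int(self.retained_indices.size)


def calibrate(
    raw: Hypercube,
    refs: ReferenceSet,
    eps: float = 1e-6,
) -> Hypercube:
    """Convert an intensity cube to reflectance, ``(Io-Id)/(Iw-Id)``.

    Parameters
    ----------
    raw : Hypercube
        Intensity cube Io, shape (y, x, bands).
    refs : ReferenceSet
        White/dark references with matching x and band dimensions; full
        cubes are reduced to per-(x, band) profiles over y.
    eps : float
        Denominator guard, as a fraction of the white-minus-dark dynamic
        range: pixels where ``|Iw - Id|`` falls below ``eps * range`` are
        set to 0 reflectance and counted in the log (dead sensor pixels
        must not poison seed means).
    """
    white, dark = refs.profiles()
    if white.shape[1] != raw.n_bands:
        raise ValueError(
            f"reference band count {white.shape[1]} does not match cube bands {raw.n_bands}"
        )
    if white.shape[0] != raw.n_samples:
        if white.shape[0] == 1:
            pass  # single-column profile broadcasts
        else:
            raise ValueError(
                f"reference sample width {white.shape[0]} does not match cube width {raw.n_samples}"
            )

    denom = white - dark
    scale = float(np.max(np.abs(denom))) or 1.0
    degenerate = np.abs(denom) < eps * scale
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("calibrate: %d degenerate reference pixels set to 0 reflectance", n_degenerate)
    safe_denom = np.where(degenerate, 1.0, denom)

    ic = (raw.data.astype(float) - dark[None, :, :]) / safe_denom[None, :, :]
    if n_degenerate:
        ic[:, degenerate] = 0.0

    return Hypercube(
        data=ic,
        wavelengths_nm=raw.wavelengths_nm,
        interleave=raw.interleave,
        dtype_code=5,
        source_path=raw.source_path,
        is_reflectance=True,
        wavelengths_synthetic=raw.wavelengths_synthetic,
    )


def trim_bands(
    cube: Hypercube,
    lo_nm: float = DEFAULT_TRIM_LO_NM,
    hi_nm: float = DEFAULT_TRIM_HI_NM,
) -> tuple[Hypercube, BandWindow]:
    """Keep exactly the bands whose centre wavelength w satisfies lo <= w <= hi."""
    if lo_nm >= hi_nm:
        raise ValueError(f"lo_nm {lo_nm} must be < hi_nm {hi_nm}")
    wl = cube.wavelengths_nm
    keep = np.nonzero((wl >= lo_nm) & (wl <= hi_nm))[0]
    if keep.size == 0:
        raise ValueError(
            f"window [{lo_nm}, {hi_nm}] nm retains no bands of the cube's "
            f"{wl[0]:.1f}-{wl[-1]:.1f} nm range"
        )
    window = BandWindow(lo_nm=lo_nm, hi_nm=hi_nm, retained_indices=keep)
    trimmed = Hypercube(
        data=cube.data[:, :, keep[0] : keep[-1] + 1],
        wavelengths_nm=wl[keep],
        interleave=cube.interleave,
        dtype_code=cube.dtype_code,
        source_path=cube.source_path,
        is_reflectance=cube.is_reflectance,
        wavelengths_synthetic=cube.wavelengths_synthetic,
    )
    return trimmed, window


def trim_bands_fraction(cube: Hypercube, fraction: float = 0.05) -> tuple[Hypercube, BandWindow]:
    """Drop ``ceil(fraction * L)`` bands at each spectral end."""
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    n_drop = math.ceil(fraction * cube.n_bands)
    keep = np.arange(n_drop, cube.n_bands - n_drop)
    if keep.size == 0:
        raise ValueError(f"fraction {fraction} retains no bands")
    wl = cube.wavelengths_nm
    window = BandWindow(lo_nm=wl[keep[0]], hi_nm=wl[keep[-1]], retained_indices=keep)
    trimmed = Hypercube(
        data=cube.data[:, :, keep[0] : keep[-1] + 1],
        wavelengths_nm=wl[keep],
        interleave=cube.interleave,
        dtype_code=cube.dtype_code,
        source_path=cube.source_path,
        is_reflectance=cube.is_reflectance,
        wavelengths_synthetic=cube.wavelengths_synthetic,
    )
    return trimmed, window
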