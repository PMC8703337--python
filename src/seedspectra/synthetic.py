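"""Synthetic seed-tray scenes with planted ground truth.

Emulates a push-broom hyperspectral acquisition of seeds on a
black-painted platform: a dark background near the dark-reference level,
ellipse-shaped seeds (optionally overlapping) whose pixel intensities are
white-scaled group reflectance curves plus independent Gaussian noise, and
matching white/dark reference cubes, so that the full pipeline —
calibration, segmentation, extraction, classification — can be exercised
end-to-end with known answers.

Two seed groups are planted. The default curves mimic the empirical
control / heat-stress (HS) contrast: HS reflectance sits above control
across the spectrum except in a 671-771 nm window where the two groups
are nearly indistinguishable, with the gap opening to >= 0.03 reflectance
above 1000 nm. A second curve pair (`planted_signal_curves`) confines the
group difference strictly to a chosen wavelength interval, for
band-importance recovery experiments.

What the generator does NOT emulate: specular highlights, shadows, point
spread, husk texture, or radiometric drift — tests passing here show the
algorithms are correct, not that real imagery is this clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .calibration import ReferenceSet
from .envi import Hypercube, write_envi
from .segmentation import EllipseParams, SeedMask

logger = logging.getLogger(__name__)

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "default_wavelengths",
    "default_group_curves",
    "planted_signal_curves",
    "generate_scene",
    "scene_to_envi",
    "match_seeds",
]


def default_wavelengths(n_bands: int = 60, lo_nm: float = 600.0, hi_nm: float = 1700.0) -> np.ndarray:
    """Evenly spaced band centres, endpoints inclusive (desk-scale default 60)."""
    return np.linspace(lo_nm, hi_nm, n_bands)


def full_sensor_wavelengths() -> np.ndarray:
    """Full-sensor grid: 268 bands over 600-1700 nm."""
    return default_wavelengths(268)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def default_group_curves(wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(control, HS) reflectance curves over *wavelengths*.

    Control is a typical seed spectrum: low in the visible, rising through
    the red edge, with a water-absorption dip near 1450 nm. HS adds a
    smooth non-negative offset that is < 0.01 inside 671-771 nm and
    >= 0.03 everywhere above 1000 nm.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be ascending")
    control = 0.15 + 0.35 * _sigmoid((wl - 730.0) / 60.0) - 0.08 * np.exp(-(((wl - 1450.0) / 40.0) ** 2))
    gap = 0.05 * _sigmoid((wl - 880.0) / 55.0)
    hs = control + gap
    return np.clip(control, 0.0, 1.0), np.clip(hs, 0.0, 1.0)


def planted_signal_curves(
    wavelengths: np.ndarray,
    lo_nm: float = 1000.0,
    hi_nm: float = 1600.0,
    amplitude: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """(control, HS) curves whose difference is confined to [lo_nm, hi_nm].

    The group gap is a Gaussian bump centred mid-interval whose tails are
    < 1e-3 of the amplitude at the interval edges, so any detectable group
    signal lies strictly inside the interval.
    """
    wl = np.asarray(wavelengths, dtype=float)
    control = 0.30 + 0.02 * _sigmoid((wl - 900.0) / 200.0)
    centre = 0.5 * (lo_nm + hi_nm)
    width = (hi_nm - lo_nm) / 2.0 / 2.65  # edge tail = exp(-2.65^2) < 1e-3
    gap = amplitude * np.exp(-(((wl - centre) / width) ** 2))
    return control, control + gap


@dataclass
class SceneSpec:
    """Parameters of one synthetic tray scene.

    Intensity counts follow ``Io = Id + R * (Iw - Id)`` with R the planted
    reflectance plus N(0, noise_sd^2) pixel-band noise (reflectance
    units); cubes are quantised to uint16 like a real 12-bit sensor.
    """

    nx: int = 200
    ny: int = 200
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelengths)
    n_seeds: int = 12
    semi_major_range: tuple[float, float] = (8.0, 14.0)
    semi_minor_range: tuple[float, float] = (5.0, 9.0)
    overlap_fraction: float = 0.0
    n_overlapping_pairs: int = 0
    group_curves: tuple[np.ndarray, np.ndarray] | None = None  # (control, hs)
    background_reflectance: float = 0.02
    white_level: float = 3000.0
    dark_level: float = 100.0
    noise_sd: float = 0.01
    n_reference_lines: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if not 0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.group_curves is None:
            self.group_curves = default_group_curves(self.wavelengths_nm)
        c, h = self.group_curves
        if len(c) != self.wavelengths_nm.size or len(h) != self.wavelengths_nm.size:
            raise ValueError("group curves must be defined on the full wavelength grid")


@dataclass
class GroundTruth:
    """Planted answers for one scene."""

    labels: np.ndarray  # truth label image, 0 = background, 1..n_seeds
    group_labels: np.ndarray  # per seed, 0 = control, 1 = HS (index 0 <-> seed 1)
    ellipses: list[EllipseParams]
    control_curve: np.ndarray
    hs_curve: np.ndarray
    wavelengths_nm: np.ndarray

    @property
    def n_seeds(self) -> int:
        return len(self.ellipses)

    def as_seed_mask(self) -> SeedMask:
        return SeedMask(labels=self.labels, ellipses={i + 1: e for i, e in enumerate(self.ellipses)})


def _ellipse_mask(shape: tuple[int, int], e: EllipseParams) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(e.theta), np.sin(e.theta)
    dx = cc - e.cx
    dy = rr - e.cy
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def _norm_radius(shape: tuple[int, int], e: EllipseParams) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(e.theta), np.sin(e.theta)
    dx = cc - e.cx
    dy = rr - e.cy
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2


def _place_seeds(spec: SceneSpec, rng: np.random.Generator) -> list[EllipseParams]:
    """Rejection-sample ellipse placements honouring the overlap constraints.

    The first ``n_overlapping_pairs`` pairs are forced to overlap by
    approximately ``overlap_fraction`` of the smaller seed's area (distance
    found by bisection); all other placements keep a >= 2 px separation so
    that distinct seeds stay 8-disconnected.
    """
    shape = (spec.ny, spec.nx)
    occupied = np.zeros(shape, dtype=bool)
    ellipses: list[EllipseParams] = []
    margin = spec.semi_major_range[1] + 2

    def sample_axes() -> tuple[float, float]:
        a = rng.uniform(*spec.semi_major_range)
        b = rng.uniform(*spec.semi_minor_range)
        if b > a:
            a, b = b, a
        return a, b

    def free_place() -> EllipseParams:
        for _ in range(200):
            a, b = sample_axes()
            e = EllipseParams(
                cx=rng.uniform(margin, spec.nx - margin),
                cy=rng.uniform(margin, spec.ny - margin),
                a=a,
                b=b,
                theta=rng.uniform(0, np.pi),
            )
            m = _ellipse_mask(shape, e)
            if not np.any(ndimage.binary_dilation(m, iterations=2) & occupied):
                return e
        raise RuntimeError("could not place a seed within the overlap constraints")

    n_pair_members = 2 * min(spec.n_overlapping_pairs, spec.n_seeds // 2)
    i = 0
    while i < spec.n_seeds:
        e1 = free_place()
        m1 = _ellipse_mask(shape, e1)
        if i + 1 < n_pair_members:
            e2 = _place_partner(spec, rng, e1, occupied, shape)
            occupied |= m1 | _ellipse_mask(shape, e2)
            ellipses.extend([e1, e2])
            i += 2
        else:
            occupied |= m1
            ellipses.append(e1)
            i += 1
    return ellipses


def _place_partner(
    spec: SceneSpec,
    rng: np.random.Generator,
    e1: EllipseParams,
    occupied: np.ndarray,
    shape: tuple[int, int],
) -> EllipseParams:
    """Place a second ellipse overlapping e1 by ~overlap_fraction of the smaller area."""
    target = spec.overlap_fraction
    m1 = _ellipse_mask(shape, e1)
    for _ in range(50):
        a = rng.uniform(*spec.semi_major_range)
        b = rng.uniform(*spec.semi_minor_range)
        if b > a:
            a, b = b, a
        phi = rng.uniform(0, 2 * np.pi)
        theta = rng.uniform(0, np.pi)

        def at(d: float) -> EllipseParams:
            return EllipseParams(
                cx=e1.cx + d * np.cos(phi), cy=e1.cy + d * np.sin(phi), a=a, b=b, theta=theta
            )

        def overlap(d: float) -> float:
            m2 = _ellipse_mask(shape, at(d))
            inter = int((m1 & m2).sum())
            return inter / max(1, min(m1.sum(), m2.sum()))

        lo, hi = 0.5 * e1.b, e1.a + a + 2
        if overlap(hi) > 0:  # direction runs off other seeds; retry
            continue
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if overlap(mid) > target:
                lo = mid
            else:
                hi = mid
        d = 0.5 * (lo + hi)
        e2 = at(d)
        ov = overlap(d)
        m2 = _ellipse_mask(shape, e2)
        inside = (
            e2.cx - a > 1 and e2.cx + a < spec.nx - 1 and e2.cy - a > 1 and e2.cy + a < spec.ny - 1
        )
        clash = np.any(ndimage.binary_dilation(m2, iterations=2) & occupied)
        if inside and not clash and 0.25 * target <= ov <= 1.2 * target + 1e-9:
            return e2
    raise RuntimeError("could not place an overlapping partner seed")


def generate_scene(spec: SceneSpec) -> tuple[Hypercube, ReferenceSet, GroundTruth]:
    """Render a scene; fully reproducible from ``spec.rng_seed``.

    Returns the raw intensity cube (uint16 counts), the matching
    white/dark reference set, and the planted ground truth. The references
    are consistent with the rendering model, so calibration recovers the
    planted reflectance curves in expectation.
    """
    rng = np.random.default_rng(spec.rng_seed)
    wl = spec.wavelengths_nm
    L = wl.size
    shape = (spec.ny, spec.nx)

    ellipses = _place_seeds(spec, rng)
    n = len(ellipses)
    # balanced group assignment, randomly permuted
    groups = np.zeros(n, dtype=int)
    groups[: n // 2] = 1
    rng.shuffle(groups)

    # truth ownership: smallest normalised ellipse radius wins contested pixels
    radius = np.stack([_norm_radius(shape, e) for e in ellipses])
    covered = radius <= 1.0
    any_cover = covered.any(axis=0)
    owner = np.where(any_cover, np.where(covered, radius, np.inf).argmin(axis=0) + 1, 0)
    labels = owner.astype(np.int32)

    control, hs = spec.group_curves
    curves = np.stack([control, hs])

    reflectance = np.empty((spec.ny, spec.nx, L), dtype=float)
    reflectance[:] = spec.background_reflectance
    for k in range(1, n + 1):
        sel = labels == k
        reflectance[sel, :] = curves[groups[k - 1]]
    reflectance += rng.normal(0.0, spec.noise_sd, size=reflectance.shape)

    # lamp spectrum: broad parabolic peak, as real halogen sources roll off
    lamp = 1.0 - 0.3 * (((wl - 1150.0) / 550.0) ** 2)
    white_profile = spec.white_level * lamp  # per band
    dark_profile = np.full(L, spec.dark_level)
    span = white_profile - dark_profile

    io = dark_profile + reflectance * span
    raw = Hypercube(
        data=np.clip(np.rint(io), 0, 65535).astype(np.uint16),
        wavelengths_nm=wl,
        interleave="bil",
        dtype_code=12,
        source_path=f"synthetic_seed{spec.rng_seed}",
    )

    ref_shape = (spec.n_reference_lines, spec.nx, L)
    ref_noise = 0.2 * spec.noise_sd * span
    white = np.clip(np.rint(white_profile + rng.normal(0, 1, ref_shape) * ref_noise), 0, 65535)
    dark = np.clip(np.rint(dark_profile + rng.normal(0, 1, ref_shape) * ref_noise), 0, 65535)
    refs = ReferenceSet(
        white=Hypercube(data=white.astype(np.uint16), wavelengths_nm=wl, dtype_code=12),
        dark=Hypercube(data=dark.astype(np.uint16), wavelengths_nm=wl, dtype_code=12),
    )

    truth = GroundTruth(
        labels=labels,
        group_labels=groups,
        ellipses=ellipses,
        control_curve=control,
        hs_curve=hs,
        wavelengths_nm=wl,
    )
    return raw, refs, truth


def scene_to_envi(spec: SceneSpec, out_dir: str | Path, stem: str = "scene") -> dict:
    """Write a generated scene as ENVI pairs (raw + white + dark); returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, refs, truth = generate_scene(spec)
    paths = {
        "raw": out_dir / f"{stem}.hdr",
        "white": out_dir / f"{stem}_white.hdr",
        "dark": out_dir / f"{stem}_dark.hdr",
    }
    write_envi(raw, paths["raw"])
    write_envi(refs.white, paths["white"])
    write_envi(refs.dark, paths["dark"])
    np.savetxt(out_dir / f"{stem}_truth_groups.csv", truth.group_labels, fmt="%d")
    return {k: str(v) for k, v in paths.items()}


def match_seeds(truth: GroundTruth, mask: SeedMask) -> list[tuple[int, int, float]]:
    """Match planted seeds to recovered seeds by centre distance (Hungarian).

    Returns ``[(truth_seed, recovered_seed, distance_px), ...]`` using
    1-based indices on both sides; unmatched seeds are absent.
    """
    n_t, n_r = truth.n_seeds, mask.n_seeds
    if n_t == 0 or n_r == 0:
        return []
    t_centres = np.array([(e.cx, e.cy) for e in truth.ellipses])
    r_centres = np.array(
        [
            (mask.ellipses[k].cx, mask.ellipses[k].cy)
            if k in mask.ellipses
            else mask.centroid(k)
            for k in range(1, n_r + 1)
        ]
    )
    cost = np.linalg.norm(t_centres[:, None, :] - r_centres[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r) + 1, int(c) + 1, float(cost[r, c])) for r, c in zip(rows, cols)]
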