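"""Per-seed spectral extraction: sub-hypercubes and averaged spectra.

Applying a seed mask across the band axis yields (a) one cropped hypercube
per seed, with non-seed pixels zeroed, and (b) one averaged spectrum per
seed — the per-seed record written to CSV with provenance columns
(image id, seed index, pixel count, centroid) followed by one column per
retained wavelength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .envi import Hypercube, write_envi
from .segmentation import SeedMask

logger = logging.getLogger(__name__)

__all__ = ["SeedSpectrum", "extract_seed_cubes", "mean_spectra", "write_outputs", "read_spectra_csv"]


@dataclass
class SeedSpectrum:
    """One seed's averaged spectrum plus provenance."""

    image_id: str
    seed_index: int
    pixel_count: int
    centroid_x: float
    centroid_y: float
    reflectance: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.shape != self.wavelengths_nm.shape:
            raise ValueError("reflectance and wavelength vectors must have equal length")


def _check_shapes(cube: Hypercube, masks: SeedMask) -> None:
    if masks.labels.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {masks.labels.shape} does not match cube x-y shape {cube.data.shape[:2]}"
        )


def extract_seed_cubes(cube: Hypercube, masks: SeedMask) -> list[Hypercube]:
    """One cropped hypercube per seed; non-seed pixels zeroed, bands intact."""
    _check_shapes(cube, masks)
    out = []
    for k in range(1, masks.n_seeds + 1):
        rows, cols = masks.pixels(k)
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        crop = np.zeros((r1 - r0 + 1, c1 - c0 + 1, cube.n_bands), dtype=cube.data.dtype)
        crop[rows - r0, cols - c0, :] = cube.data[rows, cols, :]
        out.append(
            Hypercube(
                data=crop,
                wavelengths_nm=cube.wavelengths_nm,
                interleave=cube.interleave,
                dtype_code=cube.dtype_code,
                source_path=cube.source_path,
                is_reflectance=cube.is_reflectance,
                metadata={"seed_index": k, "bbox": (int(r0), int(r1), int(c0), int(c1))},
            )
        )
    return out


def mean_spectra(cube: Hypercube, masks: SeedMask, image_id: str = "") -> list[SeedSpectrum]:
    """Arithmetic mean spectrum over each seed's pixel set, in seed order."""
    _check_shapes(cube, masks)
    image_id = image_id or Path(cube.source_path).stem or "image"
    out = []
    for k in range(1, masks.n_seeds + 1):
        rows, cols = masks.pixels(k)
        spec = cube.data[rows, cols, :].mean(axis=0, dtype=float)
        out.append(
            SeedSpectrum(
                image_id=image_id,
                seed_index=k,
                pixel_count=int(rows.size),
                centroid_x=float(cols.mean()),
                centroid_y=float(rows.mean()),
                reflectance=spec,
                wavelengths_nm=cube.wavelengths_nm,
            )
        )
    return out


def spectra_to_frame(spectra: list[SeedSpectrum]) -> pd.DataFrame:
    """Tabulate spectra: provenance columns then one column per wavelength (nm, 2 dp)."""
    if not spectra:
        return pd.DataFrame(
            columns=["image_id", "seed_index", "pixel_count", "centroid_x", "centroid_y"]
        )
    wl = spectra[0].wavelengths_nm
    rows = []
    for s in spectra:
        row = {
            "image_id": s.image_id,
            "seed_index": s.seed_index,
            "pixel_count": s.pixel_count,
            "centroid_x": s.centroid_x,
            "centroid_y": s.centroid_y,
        }
        row.update({f"{w:.2f}": float(v) for w, v in zip(wl, s.reflectance)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    spectra: list[SeedSpectrum],
    seed_cubes: list[Hypercube],
    out_dir: str | Path,
    image_id: str | None = None,
    overwrite: bool = False,
) -> dict:
    """Write one spectra CSV per image and per-seed ENVI cubes.

    Existing files are skipped (and logged) unless *overwrite* is set.
    Returns a manifest dict listing written and skipped paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_id = image_id or (spectra[0].image_id if spectra else "image")

    manifest: dict = {"image_id": image_id, "written": [], "skipped": []}

    csv_path = out_dir / f"{image_id}_spectra.csv"
    if csv_path.exists() and not overwrite:
        logger.info("skip existing %s (overwrite disabled)", csv_path)
        manifest["skipped"].append(str(csv_path))
    else:
        frame = spectra_to_frame(spectra)
        frame.to_csv(csv_path, index=False, float_format="%.8g")
        manifest["written"].append(str(csv_path))

    cube_dir = out_dir / f"{image_id}_seeds"
    for i, sc in enumerate(seed_cubes, start=1):
        hdr = cube_dir / f"seed_{i:03d}.hdr"
        if hdr.exists() and not overwrite:
            logger.info("skip existing %s (overwrite disabled)", hdr)
            manifest["skipped"].append(str(hdr))
            continue
        cube_dir.mkdir(parents=True, exist_ok=True)
        write_envi(sc, hdr)
        manifest["written"].append(str(hdr))
    return manifest


def read_spectra_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a spectra CSV back; returns (frame, wavelengths_nm)."""
    frame = pd.read_csv(path)
    meta = {"image_id", "seed_index", "pixel_count", "centroid_x", "centroid_y"}
    wl = np.array([float(c) for c in frame.columns if c not in meta])
    return frame, wl
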