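"""Reading and writing ENVI header/raw hypercube pairs.

An ENVI image is a pair of files: an ASCII header (``.hdr``) declaring the
array geometry (``samples`` = x, ``lines`` = y, ``bands``), the on-disk
interleave (BSQ/BIL/BIP), the element data type and byte order, and
optionally the per-band centre wavelengths; plus a raw binary data file.
In memory every cube is held in a fixed ``(line y, sample x, band)`` axis
order regardless of the on-disk interleave — all downstream modules rely
on that convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypercube",
    "BatchManifest",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "resolve_batch",
]

# ENVI numeric data-type codes <-> numpy dtypes (byte order applied separately)
ENVI_DTYPES = {
    1: "u1",
    2: "i2",
    3: "i4",
    4: "f4",
    5: "f8",
    12: "u2",
    13: "u4",
    14: "i8",
    15: "u8",
}
_NUMPY_TO_ENVI = {np.dtype(v): k for k, v in ENVI_DTYPES.items()}

#: Extensions tried, in order, when locating the data file companion of a header.
DATA_EXTENSIONS = ("", ".raw", ".img", ".dat")

_INTERLEAVES = ("bil", "bip", "bsq")


class EnviFormatError(ValueError):
    """Malformed or unsupported ENVI header/data pair."""


@dataclass
class Hypercube:
    """A hyperspectral image cube in ``(y, x, band)`` axis order.

    Attributes
    ----------
    data : ndarray, shape (lines, samples, bands)
        Pixel values; raw sensor counts or, after calibration, reflectance.
    wavelengths_nm : ndarray
        Strictly increasing band-centre wavelengths. If the source header
        carried no wavelength list this is the synthetic index ``1..bands``
        and ``wavelengths_synthetic`` is set.
    interleave : str
        On-disk interleave the cube was read from / will be written with.
    dtype_code : int
        ENVI data-type tag of the on-disk representation.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    interleave: str = "bil"
    dtype_code: int = 4
    source_path: str = ""
    is_reflectance: bool = False
    wavelengths_synthetic: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all cube dims must be >= 1, got {self.data.shape}")
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.shape != (self.data.shape[2],):
            raise ValueError(
                f"wavelength count {self.wavelengths_nm.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.interleave.lower() not in _INTERLEAVES:
            raise EnviFormatError(f"unsupported interleave {self.interleave!r}")
        self.interleave = self.interleave.lower()

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, band_id: int) -> np.ndarray:
        """Return the 2-D slice for a 1-based band index."""
        if not 1 <= band_id <= self.n_bands:
            raise IndexError(f"band_id {band_id} outside 1..{self.n_bands}")
        return self.data[:, :, band_id - 1]


@dataclass
class BatchManifest:
    """Ordered (header, data) file pairs resolved from an input pattern."""

    entries: list[tuple[Path, Path]]
    skipped: list[Path] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _parse_header(text: str) -> dict:
    """Parse ENVI header text into a flat key -> value/list dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic line)")
    # strip the magic line, then join continuation of brace-enclosed lists
    body = text.lstrip()[4:]
    fields: dict[str, object] = {}
    # key = { multi line list } | key = scalar
    pattern = re.compile(r"^\s*([\w ?*]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        raw = m.group(2).strip()
        pos = m.end()
        if raw.startswith("{"):
            inner = raw[1:-1] if raw.endswith("}") else raw[1:]
            items = [s.strip() for s in inner.replace("\n", " ").split(",")]
            fields[key] = [s for s in items if s]
        else:
            fields[key] = raw
    return fields


def _require_int(fields: dict, key: str) -> int:
    if key not in fields:
        raise EnviFormatError(f"header missing required field {key!r}")
    try:
        return int(str(fields[key]))
    except ValueError as exc:
        raise EnviFormatError(f"header field {key!r} is not an integer: {fields[key]!r}") from exc


def find_data_file(header_path: Path) -> Path:
    """Locate the raw data companion of *header_path*.

    Tries the header stem with no extension, then ``.raw``, ``.img``,
    ``.dat``, in that order.
    """
    header_path = Path(header_path)
    stem = header_path.with_suffix("")
    for ext in DATA_EXTENSIONS:
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(
        f"no data file found for header {header_path} "
        f"(tried extensions {', '.join(repr(e) for e in DATA_EXTENSIONS)})"
    )


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header/data pair into a :class:`Hypercube`.

    The on-disk interleave (BSQ, BIL or BIP) is resolved from the header and
    the array is reordered to the internal ``(y, x, band)`` convention.
    Headers without a wavelength list yield a synthetic ``1..bands`` index,
    flagged via ``wavelengths_synthetic``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header not found: {header_path}")
    fields = _parse_header(header_path.read_text())

    samples = _require_int(fields, "samples")
    lines = _require_int(fields, "lines")
    bands = _require_int(fields, "bands")
    dtype_code = _require_int(fields, "data type")
    if dtype_code not in ENVI_DTYPES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    interleave = str(fields.get("interleave", "bsq")).lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    byte_order = int(str(fields.get("byte order", 0)))
    offset = int(str(fields.get("header offset", 0)))

    dtype = np.dtype(("<" if byte_order == 0 else ">") + ENVI_DTYPES[dtype_code])
    data_path = find_data_file(header_path)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"data file {data_path} holds {raw.size} elements but header "
            f"declares samples*lines*bands = {samples}*{lines}*{bands} = {expected}"
        )

    if interleave == "bsq":  # (band, y, x)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (y, band, x)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (y, x, band)
        cube = raw.reshape(lines, samples, bands)

    wl = fields.get("wavelength")
    synthetic = False
    if wl is not None:
        wavelengths = np.array([float(w) for w in wl], dtype=float)
        if wavelengths.size != bands:
            raise EnviFormatError(
                f"header wavelength list has {wavelengths.size} entries for {bands} bands"
            )
    else:
        wavelengths = np.arange(1, bands + 1, dtype=float)
        synthetic = True
        logger.warning("%s: header has no wavelength list; using band index 1..%d", header_path, bands)

    return Hypercube(
        data=np.ascontiguousarray(cube),
        wavelengths_nm=wavelengths,
        interleave=interleave,
        dtype_code=dtype_code,
        source_path=str(header_path),
        wavelengths_synthetic=synthetic,
        metadata={k: v for k, v in fields.items()},
    )


def write_envi(cube: Hypercube, header_path: str | Path, data_path: str | Path | None = None) -> Path:
    """Write *cube* as an ENVI header/raw pair; returns the data path.

    The data file defaults to the header stem with ``.raw``. Integer cubes
    round-trip bit-exactly through :func:`read_envi`.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    data_path = Path(data_path)

    arr = np.asarray(cube.data)
    np_dtype = np.dtype(ENVI_DTYPES.get(cube.dtype_code, "f4"))
    if _NUMPY_TO_ENVI.get(arr.dtype) is not None:
        np_dtype = arr.dtype
    dtype_code = _NUMPY_TO_ENVI[np.dtype(np_dtype)]
    arr = arr.astype("<" + np_dtype.str.lstrip("<>|="), copy=False)

    lines, samples, bands = arr.shape
    interleave = cube.interleave
    if interleave == "bsq":
        disk = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        disk = arr.transpose(0, 2, 1)
    else:
        disk = arr

    wl_text = ",\n ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {seedspectra export}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl_text}}}\n"
    )
    header_path.parent.mkdir(parents=True, exist_ok=True)
    header_path.write_text(header)
    np.ascontiguousarray(disk).tofile(data_path)
    return data_path


def resolve_batch(pattern: str | Path) -> BatchManifest:
    """Resolve a filename glob (e.g. ``trays/*.hdr``) to header/data pairs.

    Ordering is deterministic (lexicographic). Headers whose data file is
    missing are reported in ``manifest.skipped`` and logged, never silently
    dropped; a pattern matching nothing yields an empty manifest with a
    warning rather than an error.
    """
    pattern = str(pattern)
    root = Path(pattern)
    if root.is_dir():
        headers = sorted(root.glob("*.hdr"))
    else:
        parent = Path(pattern).parent if Path(pattern).parent != Path("") else Path(".")
        headers = sorted(parent.glob(Path(pattern).name))
    entries: list[tuple[Path, Path]] = []
    skipped: list[Path] = []
    for hdr in headers:
        try:
            entries.append((hdr, find_data_file(hdr)))
        except FileNotFoundError:
            logger.warning("skipping %s: no companion data file", hdr)
            skipped.append(hdr)
    if not entries:
        logger.warning("pattern %r matched no usable header/data pairs", pattern)
    return BatchManifest(entries=entries, skipped=skipped)
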