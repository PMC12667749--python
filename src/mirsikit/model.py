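"""Shared domain types for mid-infrared spectrochemical imaging (MIRSI) data.

The unit of acquisition is a hyperspectral cube: an H x W image where every
pixel carries an absorbance spectrum on a common, evenly spaced wavenumber
axis (the mid-IR fingerprint region, by default 950-1800 cm^-1 at 2 cm^-1
spacing, 426 points).  This module defines the wavenumber grid, spectra and
spectrum collections, cube containers with FF/FFPE class metadata, reference
band definitions, and serialization to ENVI (text header + flat binary) and
HDF5 containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("kidney", "liver")
PREPS = ("FF", "FFPE")

#: Default fingerprint-region axis: 950-1800 cm^-1 at 2 cm^-1 -> 426 points.
DEFAULT_GRID_START = 950.0
DEFAULT_GRID_STOP = 1800.0
DEFAULT_GRID_STEP = 2.0


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced, strictly ascending spectral axis in cm^-1."""

    start: float
    stop: float
    step: float

    @property
    def values(self) -> np.ndarray:
        n = len(self)
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        if self.stop == self.start:
            return 1
        return int(round((self.stop - self.start) / self.step)) + 1

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber`` (must lie in range)."""
        if not (self.start - self.step / 2 <= wavenumber <= self.stop + self.step / 2):
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside grid "
                f"[{self.start}, {self.stop}]"
            )
        return int(round((wavenumber - self.start) / self.step))

    def trimmed(self, n_per_edge: int) -> "WavenumberGrid":
        """Grid with ``n_per_edge`` points removed from each end."""
        if 2 * n_per_edge >= len(self):
            raise ValueError(
                f"cannot trim {n_per_edge} points per edge from a "
                f"{len(self)}-point grid"
            )
        return WavenumberGrid(
            self.start + n_per_edge * self.step,
            self.stop - n_per_edge * self.step,
            self.step,
        )


def make_grid(start: float, stop: float, step: float) -> WavenumberGrid:
    """Construct a validated evenly spaced wavenumber grid.

    The span ``stop - start`` must be an integer multiple of ``step`` (within
    1e-9 relative tolerance); ``step`` must be positive.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if stop < start:
        raise ValueError(f"stop ({stop}) must be >= start ({start})")
    span = stop - start
    n_steps = round(span / step)
    if abs(span - n_steps * step) > 1e-9 * max(1.0, abs(span)):
        raise ValueError(
            f"span {span} cm^-1 is not an integer multiple of step {step} cm^-1"
        )
    return WavenumberGrid(float(start), float(stop), float(step))


def default_grid() -> WavenumberGrid:
    return make_grid(DEFAULT_GRID_START, DEFAULT_GRID_STOP, DEFAULT_GRID_STEP)


@dataclass(frozen=True)
class ClassLabel:
    """Sample class: tissue type crossed with preparation protocol."""

    tissue: str  # "kidney" | "liver"
    prep: str    # "FF" | "FFPE"

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.prep not in PREPS:
            raise ValueError(f"prep must be one of {PREPS}, got {self.prep!r}")

    @property
    def key(self) -> str:
        return f"{self.tissue}-{self.prep}"


ALL_CLASSES = tuple(ClassLabel(t, p) for t in TISSUES for p in PREPS)


@dataclass
class Spectrum:
    """A single absorbance spectrum aligned to a wavenumber grid."""

    grid: WavenumberGrid
    absorbance: np.ndarray

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1 or len(self.absorbance) != len(self.grid):
            raise ValueError(
                f"absorbance length {self.absorbance.shape} does not match "
                f"grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


@dataclass
class SpectrumSet:
    """A matrix of spectra sampled from one ROI, with pixel provenance."""

    grid: WavenumberGrid
    matrix: np.ndarray            # n_spectra x n_wavenumbers
    pixel_ids: np.ndarray         # n_spectra x 2 (row, col)
    roi_id: str
    class_label: ClassLabel

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.pixel_ids = np.asarray(self.pixel_ids, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix shape {self.matrix.shape} incompatible with grid "
                f"length {len(self.grid)}"
            )
        if self.pixel_ids.shape != (self.matrix.shape[0], 2):
            raise ValueError("pixel_ids must be (n_spectra, 2) row/col pairs")
        keys = {tuple(p) for p in self.pixel_ids.tolist()}
        if len(keys) != len(self.pixel_ids):
            raise ValueError(f"pixel_ids not unique within ROI {self.roi_id}")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.matrix.mean(axis=0))


@dataclass
class HyperspectralCube:
    """One ROI acquisition: H x W pixels x B wavenumbers of absorbance."""

    grid: WavenumberGrid
    data: np.ndarray              # H x W x B
    class_label: ClassLabel
    roi_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        h, w, b = self.data.shape
        if b != len(self.grid):
            raise ValueError(
                f"cube has {b} bands but grid has {len(self.grid)} points"
            )
        if h < 8 or w < 8:
            raise ValueError(f"cube spatial dims must be >= 8, got {h}x{w}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def band_image(self, wavenumber: float) -> np.ndarray:
        """Single-wavenumber intensity image at the nearest grid point."""
        idx = self.grid.index_of(wavenumber)
        actual = self.grid.values[idx]
        if actual != wavenumber:
            logger.info(
                "requested band %.1f cm^-1 resolved to nearest grid point %.1f",
                wavenumber, actual,
            )
        return self.data[:, :, idx]


@dataclass(frozen=True)
class BandDefinition:
    """A reference vibrational band: assignment, center, integration window."""

    assignment: str
    center: float
    window_low: float
    window_high: float

    def __post_init__(self):
        if not (self.window_low < self.center < self.window_high):
            raise ValueError(
                f"band {self.assignment}@{self.center}: window "
                f"[{self.window_low}, {self.window_high}] must bracket the center"
            )


def _validate_band_list(bands: Sequence[BandDefinition]) -> list[BandDefinition]:
    bands = sorted(bands, key=lambda b: b.center)
    for left, right in zip(bands, bands[1:]):
        # windows may touch but must not cross a neighbor's center
        if left.window_high > right.center or right.window_low < left.center:
            raise ValueError(
                f"integration windows of {left.assignment}@{left.center} and "
                f"{right.assignment}@{right.center} cross a neighboring center"
            )
    return list(bands)


def load_band_table(path: str | Path) -> list[BandDefinition]:
    """Load a CSV band table (columns assignment,center,window_low,window_high).

    Returns bands sorted by center.  An empty table yields an empty list.
    """
    df = pd.read_csv(path)
    required = {"assignment", "center", "window_low", "window_high"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"band table {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    bands = [
        BandDefinition(str(r.assignment), float(r.center),
                       float(r.window_low), float(r.window_high))
        for r in df.itertuples()
    ]
    return _validate_band_list(bands)


def default_band_table() -> list[BandDefinition]:
    """The packaged reference band table (15 literature bands + the 1026 cm^-1
    fixation-artifact band), with +/-12 cm^-1 windows truncated at midpoints
    between close neighbors."""
    with resources.as_file(resources.files("mirsikit.data") / "bands.csv") as p:
        return load_band_table(p)


# ---------------------------------------------------------------------------
# Serialization: ENVI (.hdr + raw binary) and HDF5 containers
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}


def _envi_data_path(hdr_path: Path) -> Path:
    for suffix in (".img", ".raw", ".dat", ""):
        cand = hdr_path.with_suffix(suffix)
        if cand.exists() and cand != hdr_path:
            return cand
    return hdr_path.with_suffix(".img")


def write_cube_envi(cube: HyperspectralCube, hdr_path: str | Path) -> None:
    """Write a cube as an ENVI header + BSQ float64 binary pair."""
    hdr_path = Path(hdr_path)
    data_path = hdr_path.with_suffix(".img")
    wl = ", ".join(f"{v:g}" for v in cube.grid.values)
    header = "\n".join([
        "ENVI",
        "description = {MIRSI absorbance cube}",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {len(cube.grid)}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = cm-1",
        f"wavelength = {{{wl}}}",
        f"tissue = {cube.class_label.tissue}",
        f"prep = {cube.class_label.prep}",
        f"roi id = {cube.roi_id}",
        "",
    ])
    hdr_path.write_text(header)
    # BSQ: band-sequential -> (bands, lines, samples)
    np.ascontiguousarray(
        cube.data.transpose(2, 0, 1).astype("<f8")
    ).tofile(data_path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines()[1:]:
        line = raw.strip()
        if not line:
            continue
        if in_braces:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).strip("{} ")
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = (s.strip() for s in line.partition("="))
        key = key.lower()
        if val.startswith("{") and not val.endswith("}"):
            buf = [val]
            in_braces = True
        else:
            fields[key] = val.strip("{} ")
    return fields


def read_cube_envi(hdr_path: str | Path) -> HyperspectralCube:
    """Read an ENVI header + binary cube (BSQ, BIL or BIP interleave)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    interleave = fields.get("interleave", "bsq").lower()

    raw = np.fromfile(_envi_data_path(hdr_path), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI payload has {raw.size} values but header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")

    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].split(",")], dtype=float
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )
    data = np.asarray(data, dtype=float)
    if len(wavelengths) > 1 and wavelengths[1] < wavelengths[0]:
        logger.info("descending wavenumber axis in %s reversed on read", hdr_path)
        wavelengths = wavelengths[::-1]
        data = data[:, :, ::-1]
    step = wavelengths[1] - wavelengths[0] if len(wavelengths) > 1 else 1.0
    grid = make_grid(wavelengths[0], wavelengths[-1], step)
    if not np.allclose(grid.values, wavelengths, rtol=1e-9):
        raise ValueError("wavelength axis is not evenly spaced")
    label = ClassLabel(fields.get("tissue", "kidney"), fields.get("prep", "FF"))
    return HyperspectralCube(grid, data, label, fields.get("roi id", "roi"))


def write_cube_h5(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube to an HDF5 container (dataset 'absorbance' + attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("absorbance", data=cube.data)
        ds.attrs["wavenumbers"] = cube.grid.values
        ds.attrs["tissue"] = cube.class_label.tissue
        ds.attrs["prep"] = cube.class_label.prep
        ds.attrs["roi_id"] = cube.roi_id


def read_cube_h5(path: str | Path) -> HyperspectralCube:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["absorbance"]
        data = ds[()]
        wn = np.asarray(ds.attrs["wavenumbers"], dtype=float)
        tissue = str(ds.attrs["tissue"])
        prep = str(ds.attrs["prep"])
        roi_id = str(ds.attrs["roi_id"])
    if data.shape[2] != len(wn):
        raise ValueError(
            f"dataset has {data.shape[2]} bands but {len(wn)} wavenumbers"
        )
    if len(wn) > 1 and wn[1] < wn[0]:
        logger.info("descending wavenumber axis in %s reversed on read", path)
        wn = wn[::-1]
        data = data[:, :, ::-1]
    step = wn[1] - wn[0] if len(wn) > 1 else 1.0
    grid = make_grid(wn[0], wn[-1], step)
    return HyperspectralCube(grid, data, ClassLabel(tissue, prep), roi_id)


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube; format chosen by extension (.hdr -> ENVI, .h5 -> HDF5)."""
    path = Path(path)
    if path.suffix == ".hdr":
        write_cube_envi(cube, path)
    elif path.suffix in (".h5", ".hdf5"):
        write_cube_h5(cube, path)
    else:
        raise ValueError(f"unknown cube format for {path} (use .hdr or .h5)")


def read_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    if path.suffix == ".hdr":
        return read_cube_envi(path)
    elif path.suffix in (".h5", ".hdf5"):
        return read_cube_h5(path)
    raise ValueError(f"unknown cube format for {path} (use .hdr or .h5)")
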