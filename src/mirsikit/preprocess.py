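"""Preprocessing of spectrometric imaging data.

Stages: (1) tissue/background segmentation by Otsu thresholding of a single
mid-IR band image (default 1608 cm^-1); (2) calibration of the detection noise
scale sigma from the discarded off-tissue pixels; (3) rubberband (lower convex
hull) baseline correction to remove broad scattering contributions; (4) seeded
random sampling of tissue-associated pixel spectra.

On the noise scale: the off-tissue pixels are the noise reference.  Detection
downstream tests individual pixel spectra, so sigma must measure the noise of
a *single* spectrum's Savitzky-Golay second derivative.  Averaging the
background pixels first would suppress uncorrelated detector noise by
sqrt(n_background) and leave a reference ~30x too permissive for per-pixel
3-sigma calling; sigma is therefore the mean across off-tissue pixels of each
pixel's second-derivative standard deviation, computed on the same trimmed
support as the peak test.  The mean background spectrum itself is still
reported in BackgroundStats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu

from .model import HyperspectralCube, Spectrum, SpectrumSet, WavenumberGrid

DEFAULT_MASK_BAND = 1608.0  # cm^-1, strong protein band used for segmentation


@dataclass
class BackgroundStats:
    """Noise reference derived from off-tissue pixels."""

    background_spectrum: Spectrum   # mean of off-tissue pixels
    sigma: float                    # single-spectrum 2nd-derivative noise scale
    n_background_pixels: int
    mask_band: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_background_pixels < 1:
            raise ValueError("need at least one background pixel")


@dataclass
class BaselineResult:
    baseline: Spectrum
    corrected: Spectrum


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance on a 256-bin histogram."""
    values = np.asarray(values, dtype=float).ravel()
    if np.ptp(values) == 0:
        raise ValueError(
            "all intensities identical: Otsu threshold (and mask) undefined"
        )
    return float(threshold_otsu(values, nbins=256))


def tissue_mask(
    cube: HyperspectralCube, mask_band: float = DEFAULT_MASK_BAND
) -> tuple[np.ndarray, float]:
    """Segment tissue vs background on the band image at ``mask_band``.

    Returns (boolean tissue mask, threshold).  Tissue pixels are those whose
    band-image intensity exceeds the Otsu threshold; both classes must be
    non-empty.
    """
    image = cube.band_image(mask_band)
    thr = otsu_threshold(image)
    mask = image > thr
    if not mask.any() or mask.all():
        raise ValueError(
            f"degenerate segmentation at {mask_band} cm^-1: "
            f"{int(mask.sum())} tissue / {int((~mask).sum())} background pixels"
        )
    return mask, thr


def background_stats(
    cube: HyperspectralCube,
    mask: np.ndarray,
    sg_window: int = 13,
    sg_order: int = 2,
    trim_per_edge: int | None = None,
    mask_band: float = DEFAULT_MASK_BAND,
) -> BackgroundStats:
    """Estimate the 3-sigma-rule noise scale from off-tissue pixels.

    ``trim_per_edge`` defaults to ``sg_window`` so the noise estimate lives on
    the same trimmed support as the downstream peak test.
    """
    if trim_per_edge is None:
        trim_per_edge = sg_window
    bg = cube.data[~np.asarray(mask, dtype=bool)]
    if bg.shape[0] == 0:
        raise ValueError("no background pixels: cannot calibrate noise")
    step = cube.grid.step
    deriv = savgol_filter(
        bg, window_length=sg_window, polyorder=sg_order, deriv=2,
        delta=step, axis=1,
    )
    core = deriv[:, trim_per_edge:-trim_per_edge]
    sigma = float(np.mean(np.std(core, axis=1)))
    mean_bg = Spectrum(cube.grid, bg.mean(axis=0))
    return BackgroundStats(mean_bg, sigma, bg.shape[0], mask_band)


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of the point sequence (monotone chain)."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j->i
            if (y[k] - y[j]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[k] - x[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull, dtype=int)


def rubberband_baseline(grid: WavenumberGrid, absorbance: np.ndarray) -> np.ndarray:
    """Rubberband baseline: lower convex hull, linearly interpolated, anchored
    at both endpoints."""
    y = np.asarray(absorbance, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("rubberband correction needs a 1-D spectrum of >= 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("rubberband correction requires finite input")
    x = grid.values
    idx = _lower_hull_indices(x, y)
    return np.interp(x, x[idx], y[idx])


def rubberband_correct(spectrum: Spectrum) -> BaselineResult:
    """Subtract the rubberband (lower convex hull) baseline from a spectrum."""
    baseline = rubberband_baseline(spectrum.grid, spectrum.absorbance)
    corrected = spectrum.absorbance - baseline
    return BaselineResult(
        baseline=Spectrum(spectrum.grid, baseline),
        corrected=Spectrum(spectrum.grid, corrected),
    )


def rubberband_correct_matrix(grid: WavenumberGrid, matrix: np.ndarray) -> np.ndarray:
    """Row-wise rubberband correction of a spectra matrix."""
    out = np.empty_like(matrix, dtype=float)
    for i in range(matrix.shape[0]):
        out[i] = matrix[i] - rubberband_baseline(grid, matrix[i])
    return out


def sample_pixels(
    cube: HyperspectralCube,
    mask: np.ndarray,
    n: int,
    seed: int,
    correct_baseline: bool = True,
) -> SpectrumSet:
    """Sample ``n`` tissue pixel spectra uniformly without replacement.

    Sampled spectra are rubberband-corrected before analysis unless
    ``correct_baseline`` is False.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n_tissue = len(rows)
    if n > n_tissue:
        raise ValueError(
            f"requested {n} pixels but the ROI has only {n_tissue} tissue pixels"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_tissue, size=n, replace=False)
    matrix = cube.data[rows[pick], cols[pick], :]
    if correct_baseline:
        matrix = rubberband_correct_matrix(cube.grid, matrix)
    return SpectrumSet(
        grid=cube.grid,
        matrix=matrix,
        pixel_ids=np.column_stack([rows[pick], cols[pick]]),
        roi_id=cube.roi_id,
        class_label=cube.class_label,
    )
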