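"""Second-derivative sub-band analysis.

Absorbance spectra are differentiated twice with a Savitzky-Golay filter
(window 13 points, polynomial order 2), which sharpens overlapping vibrational
bands: absorption maxima become negative dips of the second derivative.
Filter edge effects are removed by trimming 13 points per edge (26 of the
default 426), leaving a 400-point working range.  A dip is significant when
its magnitude exceeds three times the background noise scale sigma (the
3-sigma rule, sigma calibrated from off-tissue pixels).  Per-band occurrence
counts, sum-of-Gaussians sub-band fits, composite-Simpson band integrals, and
FF-vs-FFPE percent reductions are built on those calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .model import BandDefinition, Spectrum, SpectrumSet, WavenumberGrid

SIGMA_RULE = 3.0  # significance multiple of the background noise scale


@dataclass(frozen=True)
class DerivativeParams:
    window_length: int = 13
    poly_order: int = 2
    trim_per_edge: int | None = None   # defaults to window_length

    def __post_init__(self):
        if self.window_length % 2 == 0 or self.window_length < self.poly_order + 2:
            raise ValueError(
                f"window_length must be odd and >= poly_order + 2, got "
                f"{self.window_length} (order {self.poly_order})"
            )

    @property
    def trim(self) -> int:
        return self.window_length if self.trim_per_edge is None else self.trim_per_edge


@dataclass(frozen=True)
class PeakCall:
    center: float        # cm^-1
    depth: float         # second-derivative value at the dip (negative)
    significance: float  # |depth| / sigma


@dataclass
class GaussianSubband:
    center: float
    fwhm: float
    amplitude: float


@dataclass
class GaussianFit:
    subbands: list[GaussianSubband]
    residual_rms: float
    converged: bool


@dataclass
class BandQuantification:
    band: BandDefinition
    integral_mean: float   # absorbance * cm^-1, mean over ROIs
    integral_sd: float
    integrals: np.ndarray  # per-ROI values

    def __post_init__(self):
        if self.integral_sd < 0:
            raise ValueError("integral_sd must be >= 0")


def second_derivative(
    spectrum: Spectrum, params: DerivativeParams = DerivativeParams()
) -> Spectrum:
    """Savitzky-Golay second derivative in physical units (per cm^-2), on the
    edge-trimmed grid."""
    grid = spectrum.grid
    trim = params.trim
    if len(grid) <= 2 * trim + params.window_length:
        raise ValueError(
            f"grid of {len(grid)} points too short for trim {trim} and "
            f"window {params.window_length}"
        )
    d2 = savgol_filter(
        spectrum.absorbance,
        window_length=params.window_length,
        polyorder=params.poly_order,
        deriv=2,
        delta=grid.step,
    )
    return Spectrum(grid.trimmed(trim), d2[trim:-trim])


def second_derivative_matrix(
    grid: WavenumberGrid, matrix: np.ndarray,
    params: DerivativeParams = DerivativeParams(),
) -> tuple[WavenumberGrid, np.ndarray]:
    """Row-wise SG second derivative of a spectra matrix, trimmed."""
    trim = params.trim
    d2 = savgol_filter(
        matrix, window_length=params.window_length, polyorder=params.poly_order,
        deriv=2, delta=grid.step, axis=1,
    )
    return grid.trimmed(trim), d2[:, trim:-trim]


def detect_significant_peaks(deriv: Spectrum, sigma: float) -> list[PeakCall]:
    """Strict local minima of the second derivative deeper than -3 sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0: peak significance needs a noise model")
    d = deriv.absorbance
    wn = deriv.grid.values
    interior = np.arange(1, len(d) - 1)
    is_min = (d[interior] < d[interior - 1]) & (d[interior] < d[interior + 1])
    is_sig = d[interior] < -SIGMA_RULE * sigma
    idx = interior[is_min & is_sig]
    return [
        PeakCall(float(wn[i]), float(d[i]), float(-d[i] / sigma)) for i in idx
    ]


def _call_matrix(
    grid: WavenumberGrid, d2: np.ndarray, sigma: float
) -> np.ndarray:
    """Boolean n_spectra x n_points matrix of significant-dip positions."""
    calls = np.zeros_like(d2, dtype=bool)
    calls[:, 1:-1] = (
        (d2[:, 1:-1] < d2[:, :-2])
        & (d2[:, 1:-1] < d2[:, 2:])
        & (d2[:, 1:-1] < -SIGMA_RULE * sigma)
    )
    return calls


@dataclass
class OccurrenceTable:
    """Per-band x per-ROI counts of spectra containing a significant dip
    within +/- tolerance of the band center."""

    counts: pd.DataFrame      # index: band centers; columns: roi_ids
    n_per_roi: int
    tolerance: float

    def __post_init__(self):
        if (self.counts.values < 0).any() or (self.counts.values > self.n_per_roi).any():
            raise ValueError("occurrence counts must lie in [0, n_per_roi]")


def usable_bands(
    bands: Sequence[BandDefinition],
    grid: WavenumberGrid,
    params: DerivativeParams = DerivativeParams(),
) -> list[BandDefinition]:
    """Bands whose centers lie on the edge-trimmed working range; out-of-range
    bands (e.g. 966 cm^-1 on the default grid) are dropped with a notice."""
    trimmed = grid.trimmed(params.trim)
    kept = []
    for b in bands:
        if trimmed.start <= b.center <= trimmed.stop:
            kept.append(b)
        else:
            logging.getLogger(__name__).info(
                "band %s@%g cm^-1 outside the trimmed range [%g, %g]; skipped",
                b.assignment, b.center, trimmed.start, trimmed.stop,
            )
    return kept


def peak_occurrence(
    spectrum_sets: Sequence[SpectrumSet],
    bands: Sequence[BandDefinition],
    sigma: float,
    params: DerivativeParams = DerivativeParams(),
    tolerance: float = 2.0,
    n_per_roi: int = 100,
    seed: int = 0,
) -> OccurrenceTable:
    """Occurrence statistics of significant dips near reference band centers.

    From each ROI's SpectrumSet a seeded subset of ``n_per_roi`` spectra is
    drawn; a spectrum counts toward band b if any of its significant dips lies
    within +/- tolerance cm^-1 of b's center.
    """
    if not spectrum_sets:
        raise ValueError("need at least one ROI SpectrumSet")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid0 = spectrum_sets[0].grid
    trimmed = grid0.trimmed(params.trim)
    if tolerance < grid0.step:
        raise ValueError(
            f"tolerance {tolerance} cm^-1 below the grid step {grid0.step}"
        )
    for b in bands:
        if not (trimmed.start <= b.center <= trimmed.stop):
            raise ValueError(
                f"band center {b.center} cm^-1 outside the trimmed range "
                f"[{trimmed.start}, {trimmed.stop}]"
            )
    master = np.random.SeedSequence(seed)
    columns = {}
    for child, sset in zip(master.spawn(len(spectrum_sets)), spectrum_sets):
        if n_per_roi > len(sset):
            raise ValueError(
                f"n_per_roi {n_per_roi} exceeds the {len(sset)} spectra of "
                f"ROI {sset.roi_id}"
            )
        rng = np.random.default_rng(child)
        rows = rng.choice(len(sset), size=n_per_roi, replace=False)
        tgrid, d2 = second_derivative_matrix(sset.grid, sset.matrix[rows], params)
        calls = _call_matrix(tgrid, d2, sigma)
        wn = tgrid.values
        col = []
        for b in bands:
            near = np.abs(wn - b.center) <= tolerance + 1e-9
            col.append(int(calls[:, near].any(axis=1).sum()))
        columns[sset.roi_id] = col
    counts = pd.DataFrame(columns, index=[b.center for b in bands])
    return OccurrenceTable(counts, n_per_roi, tolerance)


def count_consistent_bands(
    table: OccurrenceTable, min_fraction: float = 0.45
) -> int:
    """Number of bands whose median occurrence across ROIs reaches
    ``min_fraction`` of the per-ROI spectrum count."""
    if table.counts.empty:
        return 0
    medians = table.counts.median(axis=1)
    return int((medians >= min_fraction * table.n_per_roi).sum())


def fit_gaussian_subbands(
    mean_spectrum: Spectrum,
    initial_centers: Sequence[float],
    fwhm_bounds: tuple[float, float] = (6.0, 80.0),
    center_slack: float = 4.0,
    max_restarts: int = 3,
) -> GaussianFit:
    """Least-squares fit of a sum of Gaussians to a baseline-corrected mean
    spectrum, one component per initial center (from the 3-sigma dips)."""
    centers = np.asarray(list(initial_centers), dtype=float)
    if centers.size == 0:
        raise ValueError("initial_centers is empty: run dip detection first")
    x = mean_spectrum.grid.values
    y = mean_spectrum.absorbance
    n = centers.size

    def unpack(p):
        return p[:n], p[n:2 * n], p[2 * n:]

    def model(p):
        c, w, a = unpack(p)
        return (a[:, None] * np.exp(
            -4.0 * np.log(2.0) * (x[None, :] - c[:, None]) ** 2 / w[:, None] ** 2
        )).sum(axis=0)

    amp0 = np.clip(np.interp(centers, x, y), 1e-6, None)
    lo = np.concatenate([centers - center_slack,
                         np.full(n, fwhm_bounds[0]), np.zeros(n)])
    hi = np.concatenate([centers + center_slack,
                         np.full(n, fwhm_bounds[1]), np.full(n, np.inf)])
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts):
        w0 = np.full(n, 20.0) * (1.0 if attempt == 0 else rng.uniform(0.6, 1.8))
        w0 = np.clip(w0, fwhm_bounds[0], fwhm_bounds[1])
        p0 = np.concatenate([centers, w0, amp0])
        res = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi))
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            break
    c, w, a = unpack(best.x)
    rms = float(np.sqrt(np.mean((model(best.x) - y) ** 2)))
    return GaussianFit(
        subbands=[GaussianSubband(float(ci), float(wi), float(ai))
                  for ci, wi, ai in zip(c, w, a)],
        residual_rms=rms,
        converged=bool(best.success),
    )


def band_integral(spectrum: Spectrum, band: BandDefinition) -> float:
    """Composite Simpson integral of absorbance over the band window.

    Uses the grid points inside [window_low, window_high]; when their count is
    even, Simpson covers the first odd run and the final subinterval is closed
    with a trapezoid.
    """
    x = spectrum.grid.values
    if band.window_low < x[0] - 1e-9 or band.window_high > x[-1] + 1e-9:
        raise ValueError(
            f"band window [{band.window_low}, {band.window_high}] outside the "
            f"spectral range [{x[0]}, {x[-1]}]"
        )
    sel = (x >= band.window_low - 1e-9) & (x <= band.window_high + 1e-9)
    xs, ys = x[sel], spectrum.absorbance[sel]
    if len(xs) < 3:
        raise ValueError(
            f"band window [{band.window_low}, {band.window_high}] spans fewer "
            "than 3 grid points"
        )
    if len(xs) % 2 == 1:
        return float(simpson(ys, x=xs))
    return float(
        simpson(ys[:-1], x=xs[:-1])
        + 0.5 * (ys[-2] + ys[-1]) * (xs[-1] - xs[-2])
    )


def quantify_bands(
    roi_mean_spectra: Sequence[Spectrum], bands: Sequence[BandDefinition]
) -> list[BandQuantification]:
    """Per-band Simpson integrals of per-ROI mean spectra, summarized over ROIs."""
    out = []
    for band in bands:
        vals = np.array([band_integral(s, band) for s in roi_mean_spectra])
        out.append(
            BandQuantification(band, float(vals.mean()), float(vals.std()), vals)
        )
    return out


def percent_reduction(integral_ff: float, integral_ffpe: float) -> float:
    """100 * (FF - FFPE) / FF: percent loss of a band integral under FFPE."""
    if integral_ff <= 0:
        raise ValueError(f"FF integral must be > 0, got {integral_ff}")
    return 100.0 * (integral_ff - integral_ffpe) / integral_ff
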