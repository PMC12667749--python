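"""End-to-end study orchestration: synthesize (or ingest) cubes, preprocess,
run the sub-band statistics, and the discrimination branch, with deterministic
seed fan-out and a JSON run report.

Every stage parameter defaults to the study's printed value where one exists:
mask band 1608 cm^-1, SG window 13 / order 2, 26 trimmed points, 3-sigma rule,
+/-2 cm^-1 occurrence tolerance, 100 spectra per ROI for occurrence, 2,000
sampled pixels per ROI, top-40 discriminative wavenumbers.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import discriminate as disc
from . import preprocess, subbands, synth
from .model import (
    ALL_CLASSES,
    BandDefinition,
    ClassLabel,
    HyperspectralCube,
    Spectrum,
    SpectrumSet,
    default_band_table,
    read_cube,
)
from .synth import AMIDE_I_CENTER

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one study run."""

    rois_per_class: int = 8
    mask_band: float = preprocess.DEFAULT_MASK_BAND   # 1608 cm^-1
    sg_window: int = 13
    sg_order: int = 2
    tolerance: float = 2.0           # cm^-1, occurrence matching
    n_per_roi: int = 100             # spectra per ROI for occurrence
    n_pixels: int = 2000             # sampled tissue pixels per ROI
    min_fraction: float = 0.45       # "consistently observed" median threshold
    integration_mode: str = "absorbance"  # or "second_derivative"
    pca_components: int = 20
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    top_k: int = 40
    n_embed_per_class: int = 500     # spectra per class for UMAP/importance
    seed: int = 0
    manifest: str | None = None      # CSV of existing cubes; None -> synthesize
    out_dir: str = "mirsi_out"


def validate_config(config: RunConfig) -> list[str]:
    """Return invariant violations and suspicious settings without executing."""
    findings = []
    if config.rois_per_class < 1:
        findings.append("rois_per_class must be >= 1")
    if config.sg_window % 2 == 0:
        findings.append(
            f"SG window {config.sg_window} must be odd (Savitzky-Golay requirement)"
        )
    elif config.sg_window < config.sg_order + 2:
        findings.append("SG window must be >= poly_order + 2")
    grid = synth.default_grid()
    if config.tolerance < grid.step:
        findings.append(
            f"occurrence tolerance {config.tolerance} cm^-1 below the grid "
            f"step {grid.step} cm^-1"
        )
    if not (grid.start <= config.mask_band <= grid.stop):
        findings.append(
            f"mask band {config.mask_band} cm^-1 outside the grid "
            f"[{grid.start}, {grid.stop}]"
        )
    if config.integration_mode not in ("absorbance", "second_derivative"):
        findings.append(
            f"unknown integration_mode {config.integration_mode!r}"
        )
    if config.n_per_roi > config.n_pixels:
        findings.append("n_per_roi cannot exceed n_pixels")
    if config.min_fraction <= 0 or config.min_fraction > 1:
        findings.append("min_fraction must be in (0, 1]")
    return findings


def _stage_seed(master: int, stage: int, index: int = 0) -> int:
    ss = np.random.SeedSequence([master, stage, index])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ArmResult:
    """Per-class analysis products."""

    label: ClassLabel
    spectrum_sets: list[SpectrumSet]
    roi_mean_spectra: list[Spectrum]
    sigma: float
    occurrence: subbands.OccurrenceTable
    band_count: int
    quantifications: list[subbands.BandQuantification]


def analyze_arm(
    cubes: Sequence[HyperspectralCube],
    bands: Sequence[BandDefinition],
    config: RunConfig,
) -> ArmResult:
    """Preprocess and quantify one class arm (all its ROI cubes)."""
    label = cubes[0].class_label
    params = subbands.DerivativeParams(config.sg_window, config.sg_order)
    bands = subbands.usable_bands(bands, cubes[0].grid, params)
    sets, sigmas, means = [], [], []
    for i, cube in enumerate(cubes):
        mask, _ = preprocess.tissue_mask(cube, config.mask_band)
        stats = preprocess.background_stats(
            cube, mask, config.sg_window, config.sg_order,
            mask_band=config.mask_band,
        )
        sigmas.append(stats.sigma)
        raw = preprocess.sample_pixels(
            cube, mask, config.n_pixels,
            seed=_stage_seed(config.seed, 1, zlib.crc32(cube.roi_id.encode())),
            correct_baseline=False,
        )
        # per-spectrum correction feeds occurrence/classification; the band
        # integrals use the corrected ROI mean, where the hull is not pulled
        # down by single-pixel noise minima
        corrected = preprocess.rubberband_correct_matrix(raw.grid, raw.matrix)
        sets.append(SpectrumSet(raw.grid, corrected, raw.pixel_ids,
                                raw.roi_id, raw.class_label))
        means.append(
            preprocess.rubberband_correct(
                Spectrum(raw.grid, raw.matrix.mean(axis=0))
            ).corrected
        )
    sigma = float(np.mean(sigmas))
    occurrence = subbands.peak_occurrence(
        sets, bands, sigma, params,
        tolerance=config.tolerance, n_per_roi=config.n_per_roi,
        seed=_stage_seed(config.seed, 2),
    )
    count = subbands.count_consistent_bands(occurrence, config.min_fraction)
    if config.integration_mode == "second_derivative":
        quant_spectra = [
            Spectrum(s.grid.trimmed(params.trim),
                     -subbands.second_derivative(s, params).absorbance)
            for s in means
        ]
    else:
        quant_spectra = means
    quants = subbands.quantify_bands(quant_spectra, bands)
    return ArmResult(label, sets, means, sigma, occurrence, count, quants)


def _amide_reduction(ff: ArmResult, ffpe: ArmResult) -> float:
    def amide(arm: ArmResult) -> float:
        for q in arm.quantifications:
            if q.band.center == AMIDE_I_CENTER:
                return q.integral_mean
        raise ValueError("Amide I band missing from the band table")
    return subbands.percent_reduction(amide(ff), amide(ffpe))


@dataclass
class StudyBandMetrics:
    """Quantitative sub-band summary of one synthetic study replicate."""

    band_counts: dict[str, int]          # class key -> consistent-band count
    reductions: dict[str, float]         # tissue -> Amide I percent reduction
    sigmas: dict[str, float]             # class key -> noise scale
    class_mean_spectra: dict[str, Spectrum]  # class key -> mean of ROI means
    n_sampled: dict[str, int]            # class key -> total sampled spectra


def study_band_metrics(
    seed: int,
    rois_per_class: int = 8,
    config: RunConfig | None = None,
) -> StudyBandMetrics:
    """Run the quantitative arm of the synthetic study in memory.

    Generates all four class arms with the default generator, analyzes each
    (masking, noise calibration, sampling, occurrence, integrals) and returns
    the per-class consistent-band counts and the per-tissue Amide I percent
    reductions.  Equivalent to the sub-band portion of run_study without
    touching disk.
    """
    config = config or RunConfig(rois_per_class=rois_per_class, seed=seed)
    bands = default_band_table()
    gen = synth.default_config()
    counts, sigmas, means, n_sampled = {}, {}, {}, {}
    quants: dict[ClassLabel, list[subbands.BandQuantification]] = {}
    for label in ALL_CLASSES:
        cubes = [
            synth.simulate_cube(
                gen, label, f"{label.key}-{i:02d}",
                synth.roi_seed(_stage_seed(config.seed, 0), label, i),
            )
            for i in range(rois_per_class)
        ]
        arm = analyze_arm(cubes, bands, config)
        counts[label.key] = arm.band_count
        sigmas[label.key] = arm.sigma
        means[label.key] = Spectrum(
            arm.roi_mean_spectra[0].grid,
            np.mean([s.absorbance for s in arm.roi_mean_spectra], axis=0),
        )
        n_sampled[label.key] = sum(len(s) for s in arm.spectrum_sets)
        quants[label] = arm.quantifications
    reductions = {}
    for tissue in ("kidney", "liver"):
        ff, ffpe = ClassLabel(tissue, "FF"), ClassLabel(tissue, "FFPE")

        def amide(qs):
            return next(q.integral_mean for q in qs
                        if q.band.center == AMIDE_I_CENTER)

        reductions[tissue] = subbands.percent_reduction(
            amide(quants[ff]), amide(quants[ffpe])
        )
    return StudyBandMetrics(counts, reductions, sigmas, means, n_sampled)


def _load_manifest(path: str) -> list[HyperspectralCube]:
    df = pd.read_csv(path)
    cubes = []
    for r in df.itertuples():
        p = Path(str(r.path))
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing cube file {p}")
        cubes.append(read_cube(p))
    return cubes


@dataclass
class RunReport:
    config: dict
    band_counts: dict[str, int]
    amide_reductions: dict[str, float]
    sigmas: dict[str, float]
    n_sampled_per_class: dict[str, int]
    silhouettes: dict[str, float]
    outputs: dict[str, str]
    stage_seconds: dict[str, float]
    version: str


def run_study(config: RunConfig) -> RunReport:
    """Execute synthesize/ingest -> preprocess -> subbands -> discriminate and
    write all stage outputs under config.out_dir."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid run config: " + "; ".join(findings))
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands = default_band_table()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.manifest is None:
        cubes = synth.simulate_study(
            synth.default_config(), config.rois_per_class,
            _stage_seed(config.seed, 0),
        )
    else:
        cubes = _load_manifest(config.manifest)
    timings["acquire"] = time.perf_counter() - t0

    by_class: dict[ClassLabel, list[HyperspectralCube]] = {}
    for c in cubes:
        by_class.setdefault(c.class_label, []).append(c)

    t0 = time.perf_counter()
    arms = {label: analyze_arm(cs, bands, config) for label, cs in by_class.items()}
    timings["subbands"] = time.perf_counter() - t0

    outputs: dict[str, str] = {}
    occ_frames = []
    for label, arm in arms.items():
        df = arm.occurrence.counts.copy()
        df.insert(0, "class", label.key)
        occ_frames.append(df)
    occ_path = out / "occurrence.csv"
    pd.concat(occ_frames).to_csv(occ_path, index_label="band_center")
    outputs["occurrence"] = str(occ_path)

    quant_rows = []
    for label, arm in arms.items():
        for q in arm.quantifications:
            quant_rows.append({
                "class": label.key, "assignment": q.band.assignment,
                "band_center": q.band.center,
                "integral_mean": q.integral_mean, "integral_sd": q.integral_sd,
            })
    integrals_path = out / "integrals.csv"
    pd.DataFrame(quant_rows).to_csv(integrals_path, index=False)
    outputs["integrals"] = str(integrals_path)

    reductions = {}
    for tissue in ("kidney", "liver"):
        ff, ffpe = ClassLabel(tissue, "FF"), ClassLabel(tissue, "FFPE")
        if ff in arms and ffpe in arms:
            reductions[tissue] = _amide_reduction(arms[ff], arms[ffpe])
    red_path = out / "comparison.csv"
    pd.DataFrame(
        [{"tissue": t, "band": "Amide I", "percent_reduction": v}
         for t, v in reductions.items()]
    ).to_csv(red_path, index=False)
    outputs["comparison"] = str(red_path)

    # discrimination branch on a per-class subset of z-scored spectra
    t0 = time.perf_counter()
    all_sets = [s for arm in arms.values() for s in arm.spectrum_sets]
    corr = disc.roi_correlation(all_sets)
    corr_path = out / "correlation.csv"
    corr.matrix.to_csv(corr_path)
    outputs["correlation"] = str(corr_path)

    rng = np.random.default_rng(_stage_seed(config.seed, 3))
    z_subsets = []
    for label, arm in arms.items():
        per_roi = max(1, config.n_embed_per_class // len(arm.spectrum_sets))
        for s in arm.spectrum_sets:
            rows = rng.choice(len(s), size=min(per_roi, len(s)), replace=False)
            z_subsets.append(disc.zscore_spectra(SpectrumSet(
                s.grid, s.matrix[rows], s.pixel_ids[rows], s.roi_id,
                s.class_label,
            )))
    embedding = disc.embed(
        z_subsets, config.pca_components, config.umap_neighbors,
        config.umap_min_dist, seed=_stage_seed(config.seed, 4),
    )
    emb_path = out / "embedding.csv"
    pd.DataFrame({
        "x": embedding.coordinates[:, 0], "y": embedding.coordinates[:, 1],
        "tissue": [l.tissue for l in embedding.labels],
        "prep": [l.prep for l in embedding.labels],
        "roi_id": embedding.roi_ids,
    }).to_csv(emb_path, index=False)
    outputs["embedding"] = str(emb_path)

    silhouettes = {}
    try:
        from sklearn.metrics import silhouette_score
        keys = np.array([l.key for l in embedding.labels])
        if len(set(keys)) > 1:
            silhouettes["all_classes"] = float(
                silhouette_score(embedding.coordinates, keys)
            )
        preps = np.array([l.prep for l in embedding.labels])
        if len(set(preps)) > 1:
            silhouettes["ff_vs_ffpe"] = float(
                silhouette_score(embedding.coordinates, preps)
            )
    except ValueError:
        pass

    importance_rows = []
    for tissue in ("kidney", "liver"):
        subset = [s for s in z_subsets if s.class_label.tissue == tissue]
        if len({s.class_label.prep for s in subset}) == 2:
            ranking = disc.feature_importance(
                subset, config.top_k, seed=_stage_seed(config.seed, 5),
            )
            for rank, (wn, score) in enumerate(
                zip(ranking.wavenumbers, ranking.scores), start=1
            ):
                importance_rows.append({
                    "tissue": tissue, "rank": rank,
                    "wavenumber": wn, "score": score,
                })
    imp_path = out / "importance.csv"
    pd.DataFrame(importance_rows).to_csv(imp_path, index=False)
    outputs["importance"] = str(imp_path)
    timings["discriminate"] = time.perf_counter() - t0

    report = RunReport(
        config=asdict(config),
        band_counts={l.key: a.band_count for l, a in arms.items()},
        amide_reductions=reductions,
        sigmas={l.key: a.sigma for l, a in arms.items()},
        n_sampled_per_class={
            l.key: sum(len(s) for s in a.spectrum_sets) for l, a in arms.items()
        },
        silhouettes=silhouettes,
        outputs=outputs,
        stage_seconds=timings,
        version=__version__,
    )
    (out / "report.json").write_text(json.dumps(asdict(report), indent=2))
    return report
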