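"""Spectral discrimination of tissue type and preparation protocol.

ROI-level Pearson correlation heatmaps summarize within- vs between-class
similarity of mean spectra; per-spectrum Z-score (SNV-style) normalization
followed by PCA and UMAP visualizes class structure; an L2-regularized
logistic regression on the normalized wavenumber features ranks the most
discriminative wavenumbers (top 40 by |standardized coefficient|).

Z-scoring is per spectrum (each spectrum centered to mean 0, scaled to SD 1)
rather than per wavenumber: the comparison of interest is spectral *shape*
across samples, and SNV-style scaling removes multiplicative path-length and
offset effects before the multivariate steps.  Column-wise standardization is
available via ``axis="wavenumber"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .model import ClassLabel, SpectrumSet


@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame                  # roi_id x roi_id Pearson correlations
    labels: dict[str, ClassLabel]         # roi_id -> class

    def __post_init__(self):
        m = self.matrix.values
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray               # n_spectra x 2
    labels: list[ClassLabel]
    roi_ids: list[str]
    pca_components: int
    umap_params: dict


@dataclass
class FeatureRanking:
    wavenumbers: np.ndarray               # top_k, rank order
    scores: np.ndarray                    # non-increasing |coefficient|
    top_k: int

    def __post_init__(self):
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("importance scores must be non-increasing")


def roi_correlation(spectrum_sets: Sequence[SpectrumSet]) -> CorrelationMatrix:
    """Pearson correlation between the mean spectra of all ROI pairs."""
    if len(spectrum_sets) < 2:
        raise ValueError("need at least two ROIs for a correlation matrix")
    grid = spectrum_sets[0].grid
    means, ids, labels = [], [], {}
    for s in spectrum_sets:
        if len(s.grid) != len(grid):
            raise ValueError("ROIs must share a common wavenumber grid")
        m = s.matrix.mean(axis=0)
        if np.std(m) == 0:
            raise ValueError(f"ROI {s.roi_id} has a zero-variance mean spectrum")
        means.append(m)
        ids.append(s.roi_id)
        labels[s.roi_id] = s.class_label
    corr = np.corrcoef(np.vstack(means))
    # exact symmetry / unit diagonal against floating fuzz
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(pd.DataFrame(corr, index=ids, columns=ids), labels)


def zscore_spectra(spectra: SpectrumSet, axis: str = "spectrum") -> SpectrumSet:
    """Z-score normalization: each spectrum to mean 0, SD 1 (default), or each
    wavenumber column standardized (``axis="wavenumber"``)."""
    m = spectra.matrix
    if axis == "spectrum":
        sd = m.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            row, col = (int(v) for v in spectra.pixel_ids[bad[0]])
            raise ValueError(
                f"constant spectrum at pixel ({row}, {col}) in ROI "
                f"{spectra.roi_id}: Z-score undefined"
            )
        z = (m - m.mean(axis=1, keepdims=True)) / sd[:, None]
    elif axis == "wavenumber":
        sd = m.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance wavenumber column: Z-score undefined")
        z = (m - m.mean(axis=0)) / sd
    else:
        raise ValueError(f"axis must be 'spectrum' or 'wavenumber', got {axis!r}")
    return SpectrumSet(spectra.grid, z, spectra.pixel_ids, spectra.roi_id,
                       spectra.class_label)


def embed(
    spectrum_sets: Sequence[SpectrumSet],
    n_components: int = 20,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> EmbeddingResult:
    """PCA (n_components scores) followed by a seeded 2-D UMAP embedding."""
    import umap

    X = np.vstack([s.matrix for s in spectrum_sets])
    labels = [s.class_label for s in spectrum_sets for _ in range(len(s))]
    roi_ids = [s.roi_id for s in spectrum_sets for _ in range(len(s))]
    if n_components >= X.shape[1]:
        raise ValueError(
            f"n_components {n_components} must be < n_features {X.shape[1]}"
        )
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more than {n_components} spectra, got {X.shape[0]}"
        )
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("all spectra identical: embedding undefined")
    scores = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(scores), dtype=float)
    return EmbeddingResult(
        coordinates=coords,
        labels=labels,
        roi_ids=roi_ids,
        pca_components=n_components,
        umap_params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                     "seed": seed},
    )


def feature_importance(
    spectrum_sets: Sequence[SpectrumSet],
    top_k: int = 40,
    seed: int = 0,
) -> FeatureRanking:
    """Rank wavenumbers by |logistic-regression coefficient| for FF vs FFPE.

    The model is L2-regularized logistic regression on the (already z-scored)
    full wavenumber features; importance is attributable per wavenumber.
    """
    X = np.vstack([s.matrix for s in spectrum_sets])
    y = np.concatenate([
        np.full(len(s), 1 if s.class_label.prep == "FFPE" else 0)
        for s in spectrum_sets
    ])
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance needs both FF and FFPE spectra")
    grid = spectrum_sets[0].grid
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(X, y)
    importance = np.abs(clf.coef_.ravel())
    order = np.argsort(importance)[::-1][:top_k]
    return FeatureRanking(
        wavenumbers=grid.values[order],
        scores=importance[order],
        top_k=top_k,
    )
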