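"""Hyperspectrum reconstruction and ML feature preparation.

Each cataloged cell region is used as a mask to average the signal over
the six multichannel microspectroscopy stacks, yielding a 6 x 32 matrix
per cell.  The mean spectrum of the non-cell area is subtracted to
remove background fluorescence from the medium and the setup.  For
machine learning, matrices can be Laplacian-filtered and flattened into
192-dimensional feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .catalog import Hyperspectrum, HyperspectrumCatalog
from .segmentation import LabelMap, region_catalog
from .stacks import SpectralStack

# four-neighbor discrete Laplacian (center -4, edge neighbors +1)
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class BackgroundSpectrum:
    """Mean 6 x 32 spectrum of the non-cell area and how many pixels made it."""

    matrix: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, 32):
            raise ValueError("background spectrum must be 6x32")
        if self.n_pixels <= 0:
            raise ValueError("background must average at least one pixel")


@dataclass
class FeatureVector:
    cell_id: int
    values: np.ndarray
    feature_mode: str = "raw"  # raw | laplacian
    normalization: str = "none"  # none | max1 | sum1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (192,):
            raise ValueError(f"feature vector must have 192 entries, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector has non-finite entries")


def _spectral_planes(labelmap: LabelMap, spectral: SpectralStack) -> np.ndarray:
    """Spectral data collapsed to the label map's geometry: (6, 32, *spatial).

    2D mode averages the stack over z (mean projection, kept linear);
    3D mode uses the voxels directly.
    """
    arr = spectral.intensities
    if labelmap.labels.ndim == 2:
        planes = arr.mean(axis=2)  # (6, 32, y, x)
        if planes.shape[2:] != labelmap.labels.shape:
            raise ValueError(
                f"label map {labelmap.labels.shape} does not match spectral frame {planes.shape[2:]}"
            )
        return planes
    if arr.shape[2:] != labelmap.labels.shape:
        raise ValueError(
            f"label map {labelmap.labels.shape} does not match spectral volume {arr.shape[2:]}"
        )
    return arr


def extract_hyperspectra(labelmap: LabelMap, spectral: SpectralStack) -> HyperspectrumCatalog:
    """Masked per-cell averaging over the six spectral stacks.

    For each cell k and each (excitation, emission bin), the value is
    the mean intensity over the cell's member pixels (2D) or voxels
    (3D).  Centroids come from the region catalog.
    """
    planes = _spectral_planes(labelmap, spectral)  # (6, 32, *spatial)
    labels_flat = labelmap.labels.ravel()
    n_labels = int(labels_flat.max()) + 1 if labels_flat.size else 1
    counts = np.bincount(labels_flat, minlength=n_labels)
    flat = planes.reshape(192, -1)
    sums = np.empty((192, n_labels))
    for f in range(192):
        sums[f] = np.bincount(labels_flat, weights=flat[f], minlength=n_labels)
    regions = region_catalog(labelmap)
    entries = []
    for reg in regions:
        k = reg.cell_id
        matrix = (sums[:, k] / counts[k]).reshape(6, 32)
        entries.append(Hyperspectrum(k, matrix, reg.centroid, source=labelmap.mode))
    return HyperspectrumCatalog(entries, None, spectral.config)


def estimate_background(
    labelmap: LabelMap, spectral: SpectralStack, exclusion_radius_px: int = 2
) -> BackgroundSpectrum:
    """Mean spectrum over the non-cell area.

    Cell regions are dilated by ``exclusion_radius_px`` before taking
    the complement, to keep PSF-blurred halos around cells out of the
    background estimate.
    """
    planes = _spectral_planes(labelmap, spectral)
    cell_mask = labelmap.labels > 0
    if exclusion_radius_px > 0 and cell_mask.any():
        cell_mask = ndimage.binary_dilation(
            cell_mask, iterations=exclusion_radius_px,
            structure=ndimage.generate_binary_structure(cell_mask.ndim, cell_mask.ndim),
        )
    background = ~cell_mask
    n = int(background.sum())
    if n == 0:
        raise ValueError("no background pixels left after cell exclusion")
    matrix = planes.reshape(192, -1)[:, background.ravel()].mean(axis=1).reshape(6, 32)
    return BackgroundSpectrum(matrix, n)


def subtract_background(
    catalog: HyperspectrumCatalog, background: BackgroundSpectrum | np.ndarray
) -> HyperspectrumCatalog:
    """Entrywise background subtraction, clipped at zero.

    Negative differences are clipped so relative fluorescence stays
    non-negative.  Double subtraction is refused via a provenance flag.
    """
    if catalog.provenance.get("background_subtracted"):
        raise ValueError("catalog background was already subtracted")
    bg = background.matrix if isinstance(background, BackgroundSpectrum) else np.asarray(background, dtype=float)
    if bg.shape != (6, 32):
        raise ValueError("background must be 6x32")
    entries = [
        Hyperspectrum(e.cell_id, np.clip(e.matrix - bg, 0.0, None), e.centroid, e.source)
        for e in catalog.entries
    ]
    prov = dict(catalog.provenance)
    prov["background_subtracted"] = True
    return HyperspectrumCatalog(entries, catalog.labels, catalog.config, prov)


def laplacian_filter(matrix: np.ndarray) -> np.ndarray:
    """3x3 four-neighbor Laplacian with replicate-padded borders.

    Annihilates constants (including at the borders) and highlights
    local curvature of the hyperspectrum surface.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (6, 32):
        raise ValueError(f"expected a 6x32 matrix, got {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix has non-finite entries")
    return ndimage.convolve(matrix, LAPLACIAN_KERNEL, mode="nearest")


def to_feature_vector(
    hs: Hyperspectrum | np.ndarray,
    feature_mode: str = "raw",
    normalization: str = "none",
) -> FeatureVector:
    """Flatten a hyperspectrum into the 192-dimensional ML feature vector.

    Order of operations: normalization (max1 divides by the matrix
    maximum, sum1 by its sum), optional Laplacian filtering, then
    row-major excitation-major flattening (entry (r, c) -> index 32r+c).
    """
    if isinstance(hs, Hyperspectrum):
        cell_id, matrix = hs.cell_id, hs.matrix
    else:
        cell_id, matrix = 0, np.asarray(hs, dtype=float)
    if matrix.shape != (6, 32):
        raise ValueError(f"expected a 6x32 matrix, got {matrix.shape}")
    if normalization == "max1":
        m = matrix.max()
        if m == 0:
            raise ValueError("cannot max-normalize an all-zero hyperspectrum")
        matrix = matrix / m
    elif normalization == "sum1":
        s = matrix.sum()
        if s == 0:
            raise ValueError("cannot sum-normalize an all-zero hyperspectrum")
        matrix = matrix / s
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if feature_mode == "laplacian":
        matrix = laplacian_filter(matrix)
    elif feature_mode != "raw":
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    return FeatureVector(cell_id, matrix.reshape(-1), feature_mode, normalization)


def feature_matrix(
    catalog: HyperspectrumCatalog,
    feature_mode: str = "raw",
    normalization: str = "none",
) -> tuple[np.ndarray, list[str] | None]:
    """(n, 192) feature array for a whole catalog plus its labels."""
    X = np.stack(
        [to_feature_vector(e, feature_mode, normalization).values for e in catalog.entries]
    ) if len(catalog) else np.empty((0, 192))
    return X, list(catalog.labels) if catalog.labels is not None else None
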