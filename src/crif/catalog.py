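"""Per-cell hyperspectrum records and catalog I/O.

A hyperspectrum is a cell's 6 x 32 matrix of mean fluorescence
intensities (six excitation lines, 32 emission bins) together with the
cell's identity and centroid.  Catalogs are written as one CSV row per
cell (id, centroid, optional class label, 192 intensity columns) with a
JSON sidecar carrying the spectral configuration and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SpectralConfig


@dataclass
class Hyperspectrum:
    """One cell's 6 x 32 fluorescence signature."""

    cell_id: int
    matrix: np.ndarray
    centroid: tuple[float, ...]  # (x, y) or (x, y, z), pixel units
    source: str = "2D"  # projection mode the spectrum came from

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.matrix.shape != (6, 32):
            raise ValueError(f"hyperspectrum must be 6x32, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("hyperspectrum has non-finite entries")
        if np.any(self.matrix < 0):
            raise ValueError("hyperspectrum has negative entries")
        self.centroid = tuple(float(c) for c in self.centroid)

    def flatten(self) -> np.ndarray:
        """Row-major, excitation-major flattening: entry (r, c) -> index 32r + c."""
        return self.matrix.reshape(-1)


@dataclass
class HyperspectrumCatalog:
    """A population of hyperspectra sharing one spectral configuration."""

    entries: list[Hyperspectrum] = field(default_factory=list)
    labels: list[str] | None = None  # per-entry class label
    config: SpectralConfig = field(default_factory=SpectralConfig)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.cell_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cell_ids in catalog")
        if self.labels is not None and len(self.labels) != len(self.entries):
            raise ValueError("labels length must match entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def matrices(self) -> np.ndarray:
        """(n, 6, 32) array of all hyperspectra, catalog order."""
        if not self.entries:
            return np.empty((0, 6, 32))
        return np.stack([e.matrix for e in self.entries])

    def with_label(self, label: str) -> "HyperspectrumCatalog":
        return HyperspectrumCatalog(
            list(self.entries), [label] * len(self.entries), self.config, dict(self.provenance)
        )

    def sorted_by_id(self) -> "HyperspectrumCatalog":
        order = np.argsort([e.cell_id for e in self.entries], kind="stable")
        labels = [self.labels[i] for i in order] if self.labels is not None else None
        return HyperspectrumCatalog(
            [self.entries[i] for i in order], labels, self.config, dict(self.provenance)
        )


def merge_catalogs(catalogs: list[HyperspectrumCatalog]) -> HyperspectrumCatalog:
    """Concatenate labeled catalogs, re-numbering ids to stay unique."""
    entries: list[Hyperspectrum] = []
    labels: list[str] = []
    next_id = 1
    for cat in catalogs:
        if cat.labels is None:
            raise ValueError("merge_catalogs requires labeled catalogs")
        for e, lab in zip(cat.entries, cat.labels):
            entries.append(Hyperspectrum(next_id, e.matrix, e.centroid, e.source))
            labels.append(lab)
            next_id += 1
    cfg = catalogs[0].config if catalogs else SpectralConfig()
    return HyperspectrumCatalog(entries, labels, cfg)


def population_mean(catalog: HyperspectrumCatalog) -> np.ndarray:
    """Entrywise arithmetic mean hyperspectrum of a population (6 x 32)."""
    if len(catalog) == 0:
        raise ValueError("population_mean of an empty catalog")
    return catalog.matrices().mean(axis=0)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_catalog(catalog: HyperspectrumCatalog, path) -> None:
    """Write CSV (one row per cell) + JSON sidecar with the spectral config."""
    path = Path(path)
    cfg = catalog.config
    feat_cols = cfg.feature_names()
    rows = []
    for i, e in enumerate(catalog.entries):
        row: dict = {"cell_id": e.cell_id}
        cx, cy = e.centroid[0], e.centroid[1]
        row["centroid_x"] = cx
        row["centroid_y"] = cy
        row["centroid_z"] = e.centroid[2] if len(e.centroid) > 2 else np.nan
        row["source"] = e.source
        row["label"] = catalog.labels[i] if catalog.labels is not None else ""
        row.update(zip(feat_cols, e.flatten()))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["cell_id", "centroid_x", "centroid_y", "centroid_z", "source", "label"] + feat_cols)
    df.to_csv(path, index=False)
    sidecar = {
        "config": cfg.to_dict(),
        "provenance": catalog.provenance,
        "n_cells": len(catalog),
        "has_labels": catalog.labels is not None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_catalog(path) -> HyperspectrumCatalog:
    """Invert :func:`write_catalog` to within float32 round-trip."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        with open(sidecar_file) as fh:
            sidecar = json.load(fh)
        cfg = SpectralConfig.from_dict(sidecar["config"])
        provenance = sidecar.get("provenance", {})
        has_labels = sidecar.get("has_labels", False)
    else:
        cfg, provenance, has_labels = SpectralConfig(), {}, False
    df = pd.read_csv(path)
    feat_cols = cfg.feature_names()
    missing = [c for c in feat_cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"catalog is missing {len(missing)} of {len(feat_cols)} intensity columns"
        )
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_ids in catalog file")
    entries = []
    labels: list[str] | None = [] if has_labels else None
    for _, row in df.iterrows():
        cz = row["centroid_z"]
        centroid = (
            (row["centroid_x"], row["centroid_y"])
            if pd.isna(cz)
            else (row["centroid_x"], row["centroid_y"], cz)
        )
        matrix = row[feat_cols].to_numpy(dtype=float).reshape(6, 32)
        entries.append(Hyperspectrum(int(row["cell_id"]), matrix, centroid, str(row["source"])))
        if labels is not None:
            labels.append("" if pd.isna(row["label"]) else str(row["label"]))
    return HyperspectrumCatalog(entries, labels, cfg, provenance)
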