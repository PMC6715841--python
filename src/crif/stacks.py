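"""Image-stack containers and TIFF I/O.

Reflection stacks are plain (z, y, x) multi-page TIFFs.  Spectral stacks
are five-dimensional (excitation, emission bin, z, y, x); to stay within
ordinary TIFF semantics each excitation line is written to its own
multi-page file with shape (z, emission, y, x) and a JSON manifest names
the six files plus the spectral configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .config import SpectralConfig

MANIFEST_NAME_KEY = "excitation_files"


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values (corrupt input?)")


@dataclass
class ReflectionStack:
    """A reflection-confocal z-stack; cells appear darker than background."""

    intensities: np.ndarray  # (z, y, x)
    config: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"reflection stack must be 3D (z, y, x), got {self.intensities.ndim} axes"
            )
        if min(self.intensities.shape) < 1:
            raise ValueError("empty reflection stack")
        _check_finite(self.intensities, "reflection stack")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SpectralStack:
    """Six-excitation, 32-bin confocal microspectroscopy data.

    Axis order is (excitation, emission bin, z, y, x).
    """

    intensities: np.ndarray
    config: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 5:
            raise ValueError(
                f"spectral stack must be 5D (exc, em, z, y, x), got {self.intensities.ndim} axes"
            )
        n_exc, n_em = self.intensities.shape[:2]
        if n_exc != self.config.n_excitations or n_em != self.config.n_emission_bins:
            raise ValueError(
                f"spectral axes ({n_exc}, {n_em}) do not match config "
                f"({self.config.n_excitations}, {self.config.n_emission_bins})"
            )
        _check_finite(self.intensities, "spectral stack")
        if np.any(self.intensities < 0):
            raise ValueError("spectral stack has negative intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[2:]


def write_stack(stack: ReflectionStack | SpectralStack, path) -> None:
    """Write a stack to disk (float32 in files, float64 in memory).

    Reflection stacks become one multi-page TIFF.  Spectral stacks become a
    ``.json`` manifest plus one TIFF per excitation line next to it.
    """
    path = Path(path)
    if isinstance(stack, ReflectionStack):
        tifffile.imwrite(path, stack.intensities.astype(np.float32), photometric="minisblack")
        return
    if not isinstance(stack, SpectralStack):
        raise TypeError(f"cannot write object of type {type(stack).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    files = []
    for i, exc in enumerate(stack.config.excitation_nm):
        fname = f"{stem}_exc{int(round(exc))}.tif"
        # (z, em, y, x) pages so each TIFF is a conventional multichannel z-stack
        planes = np.moveaxis(stack.intensities[i], 0, 1).astype(np.float32)
        tifffile.imwrite(path.parent / fname, planes, photometric="minisblack")
        files.append(fname)
    manifest = {MANIFEST_NAME_KEY: files, "config": stack.config.to_dict()}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_stack(
    path, kind: str, config: SpectralConfig | None = None
) -> ReflectionStack | SpectralStack:
    """Read a stack written by :func:`write_stack`.

    ``kind`` is ``"reflection"`` (a 3-axis TIFF) or ``"spectral"`` (a JSON
    manifest naming six per-excitation TIFFs).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind == "reflection":
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(
                f"{path} has {arr.ndim} axes; a reflection stack needs 3 (z, y, x)"
            )
        return ReflectionStack(arr, config or SpectralConfig())
    if kind == "spectral":
        with open(path) as fh:
            manifest = json.load(fh)
        cfg = config or SpectralConfig.from_dict(manifest["config"])
        planes = []
        for fname in manifest[MANIFEST_NAME_KEY]:
            arr = np.asarray(tifffile.imread(path.parent / fname), dtype=float)
            if arr.ndim == 3:  # single z-plane collapsed by the writer
                arr = arr[None]
            if arr.ndim != 4:
                raise ValueError(
                    f"{fname} has {arr.ndim} axes; expected (z, em, y, x)"
                )
            planes.append(np.moveaxis(arr, 1, 0))  # -> (em, z, y, x)
        return SpectralStack(np.stack(planes), cfg)
    raise ValueError(f"unknown stack kind {kind!r}")
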