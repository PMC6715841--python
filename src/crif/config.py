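"""Spectral acquisition geometry shared by every stage of the pipeline.

A CRIF acquisition interleaves one reflection-confocal scan with six
multichannel microspectroscopy scans per z-plane.  Emission is dispersed
into 32 contiguous 8-nm bins starting at 416 nm, so every cell yields a
6 (excitation) x 32 (emission) intensity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

DEFAULT_EXCITATIONS_NM = (405.0, 458.0, 488.0, 514.0, 543.0, 633.0)


@dataclass(frozen=True)
class SpectralConfig:
    """Fixed excitation/emission grid and voxel geometry of an acquisition.

    Parameters
    ----------
    excitation_nm:
        The six laser lines, in increasing wavelength order.
    emission_start_nm, emission_bin_width_nm, n_emission_bins:
        Contiguous non-overlapping emission bins; defaults cover 416-672 nm
        bin starts (416-691 nm range) in 8-nm windows.
    voxel_xyz_reflection_um, voxel_xyz_spectral_um:
        (x, y, z) voxel pitch of the reflection and spectral scans.
    acquisition_order:
        Metadata only: excitation sequence used at the microscope
        (longest-to-shortest wavelength).
    """

    excitation_nm: tuple[float, ...] = DEFAULT_EXCITATIONS_NM
    emission_start_nm: float = 416.0
    emission_bin_width_nm: float = 8.0
    n_emission_bins: int = 32
    voxel_xyz_reflection_um: tuple[float, float, float] = (0.264, 0.264, 0.674)
    voxel_xyz_spectral_um: tuple[float, float, float] = (0.264, 0.264, 0.871)
    acquisition_order: str = "longest-to-shortest"
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        exc = tuple(float(w) for w in self.excitation_nm)
        if len(exc) != 6:
            raise ValueError(f"expected exactly 6 excitation lines, got {len(exc)}")
        if any(b <= a for a, b in zip(exc, exc[1:])):
            raise ValueError("excitation wavelengths must be strictly increasing")
        if self.n_emission_bins < 1 or self.emission_bin_width_nm <= 0:
            raise ValueError("emission bins must be positive in count and width")
        for vox in (self.voxel_xyz_reflection_um, self.voxel_xyz_spectral_um):
            if any(v <= 0 for v in vox):
                raise ValueError(f"voxel dimensions must be positive, got {vox}")
        object.__setattr__(self, "excitation_nm", exc)

    @property
    def n_excitations(self) -> int:
        return len(self.excitation_nm)

    @property
    def n_features(self) -> int:
        """Length of a flattened hyperspectrum (6 x 32 = 192)."""
        return self.n_excitations * self.n_emission_bins

    def emission_bin_edges(self) -> np.ndarray:
        """(n_bins + 1,) contiguous bin edges in nm."""
        return self.emission_start_nm + self.emission_bin_width_nm * np.arange(
            self.n_emission_bins + 1, dtype=float
        )

    def emission_bin_centers(self) -> np.ndarray:
        edges = self.emission_bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])

    def feature_names(self) -> list[str]:
        """Column names for a flattened catalog row, excitation-major."""
        centers = self.emission_bin_centers()
        return [
            f"exc{int(round(exc))}_em{int(round(c))}"
            for exc in self.excitation_nm
            for c in centers
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excitation_nm"] = list(self.excitation_nm)
        d["voxel_xyz_reflection_um"] = list(self.voxel_xyz_reflection_um)
        d["voxel_xyz_spectral_um"] = list(self.voxel_xyz_spectral_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralConfig":
        d = dict(d)
        for key in ("excitation_nm", "voxel_xyz_reflection_um", "voxel_xyz_spectral_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SpectralConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
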