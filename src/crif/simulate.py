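"""Synthetic confocal scene generator.

Emulates a CRIF acquisition: microbial cells (spheres for budding yeast,
spherocylindrical rods for bacteria, ellipsoids for fission yeast) laid
out in a volume, each class carrying a distinct 6 x 32 emission
signature built from Gaussian emission components.  Rendering produces a
reflection stack in which cells are darker than the background (lower
refractive index than the coverslip), six-excitation spectral stacks
with background fluorescence, Gaussian PSF blur and Poisson + read
noise, and a noise-free ground-truth label map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import SpectralConfig
from .stacks import ReflectionStack, SpectralStack
from .segmentation import LabelMap


# ---------------------------------------------------------------------------
# signatures


@dataclass
class SpectralSignature:
    """Per-voxel 'pure' emission signature of one cell class.

    ``components`` maps an excitation row index (0-5) to a list of
    Gaussian emission components ``(amplitude, peak_nm, width_nm)``; the
    6 x 32 matrix is their evaluation at the emission bin centers.
    """

    class_name: str
    matrix: np.ndarray
    components: dict[int, list[tuple[float, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, 32):
            raise ValueError(f"signature must be 6x32, got {self.matrix.shape}")
        if np.any(self.matrix < 0):
            raise ValueError("signature entries must be non-negative")


def make_signature(
    class_name: str,
    components: dict[int, list[tuple[float, float, float]]],
    config: SpectralConfig | None = None,
) -> SpectralSignature:
    """Build a signature from Gaussian emission components.

    Row r, bin c value is sum over that row's components of
    ``amplitude * exp(-(center_c - peak)^2 / (2 width^2))``.
    """
    cfg = config or SpectralConfig()
    centers = cfg.emission_bin_centers()
    matrix = np.zeros((cfg.n_excitations, cfg.n_emission_bins))
    for row, comps in components.items():
        for amp, peak, width in comps:
            if amp < 0:
                raise ValueError(f"negative amplitude {amp} in {class_name!r}")
            if width <= 0:
                raise ValueError(f"non-positive width {width} in {class_name!r}")
            matrix[row] += amp * np.exp(-((centers - peak) ** 2) / (2.0 * width**2))
    return SpectralSignature(class_name, matrix, {k: list(v) for k, v in components.items()})


def example_signatures(config: SpectralConfig | None = None) -> dict[str, SpectralSignature]:
    """Distinct, realistic class signatures for demos and tests.

    Amplitudes are in arbitrary detector units (cell interiors reach
    ~30-60, an order of magnitude over the default background); peaks
    loosely follow flavin-like (~520-530 nm) and pigment-like long-
    wavelength emission differences between classes.
    """
    cfg = config or SpectralConfig()
    specs = {
        # rod-shaped soil bacterium, flavin-dominated short-wavelength emission
        "pseudomonas_like": {
            0: [(60.0, 520.0, 25.0)],
            1: [(45.0, 530.0, 28.0)],
            2: [(30.0, 545.0, 30.0)],
            3: [(18.0, 560.0, 30.0)],
            4: [(10.0, 590.0, 35.0)],
            5: [(4.0, 660.0, 20.0)],
        },
        # rod-shaped spore-former, red-shifted emission with a long-wavelength peak
        "paenibacillus_like": {
            0: [(30.0, 470.0, 22.0), (20.0, 620.0, 30.0)],
            1: [(25.0, 500.0, 25.0), (25.0, 630.0, 30.0)],
            2: [(20.0, 540.0, 30.0), (30.0, 640.0, 28.0)],
            3: [(15.0, 580.0, 30.0), (28.0, 650.0, 25.0)],
            4: [(12.0, 600.0, 30.0), (25.0, 655.0, 22.0)],
            5: [(20.0, 665.0, 18.0)],
        },
        # spherical budding yeast, broad NADH/flavin mix
        "budding_yeast_like": {
            0: [(55.0, 470.0, 35.0)],
            1: [(50.0, 505.0, 32.0)],
            2: [(40.0, 528.0, 30.0)],
            3: [(25.0, 548.0, 30.0)],
            4: [(14.0, 585.0, 32.0)],
            5: [(5.0, 655.0, 22.0)],
        },
        # elongated fission yeast, shifted peaks and stronger mid-excitation rows
        "fission_yeast_like": {
            0: [(30.0, 450.0, 28.0)],
            1: [(35.0, 540.0, 26.0)],
            2: [(50.0, 560.0, 26.0)],
            3: [(45.0, 575.0, 26.0)],
            4: [(30.0, 600.0, 28.0)],
            5: [(12.0, 650.0, 22.0)],
        },
    }
    return {name: make_signature(name, comps, cfg) for name, comps in specs.items()}


def stage_variants(
    signature: SpectralSignature,
    n_stages: int,
    peak_drift_nm: float = 12.0,
    amp_drift: float = 0.25,
    config: SpectralConfig | None = None,
) -> list[SpectralSignature]:
    """Growth-stage variants of a class signature.

    Emulates physiological drift: emission peaks shift by up to
    ``peak_drift_nm`` and amplitudes by up to ``amp_drift`` (fractional)
    across stages, deterministically, while the class identity remains
    recognizable.  Stage k of class X is named ``"X/stage<k>"``.
    """
    variants = []
    for k in range(n_stages):
        frac = k / max(n_stages - 1, 1)  # 0 .. 1 across stages
        comps: dict[int, list[tuple[float, float, float]]] = {}
        for row, row_comps in signature.components.items():
            shifted = []
            for j, (amp, peak, width) in enumerate(row_comps):
                direction = 1.0 if (row + j) % 2 == 0 else -1.0
                shifted.append(
                    (
                        amp * (1.0 + amp_drift * direction * frac),
                        peak + peak_drift_nm * direction * frac,
                        width,
                    )
                )
            comps[row] = shifted
        variants.append(
            make_signature(f"{signature.class_name}/stage{k}", comps, config)
        )
    return variants


# ---------------------------------------------------------------------------
# scene ground truth


@dataclass
class ShapeSpec:
    """Geometry template for one cell class."""

    class_name: str
    shape: str  # sphere | rod | ellipsoid
    size_um: tuple[float, ...]
    # sphere: (radius,); rod: (total_length, radius); ellipsoid: semi-axes (a, b, c)
    scale: float = 1.0  # multiplies the class signature per cell

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "rod", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(s <= 0 for s in self.size_um):
            raise ValueError("cell sizes must be positive")

    def max_radius_um(self) -> float:
        if self.shape == "sphere":
            return self.size_um[0]
        if self.shape == "rod":
            return self.size_um[0] / 2.0
        return max(self.size_um)


@dataclass
class CellTruth:
    cell_id: int
    class_name: str
    shape: str
    center_um: tuple[float, float, float]
    size_um: tuple[float, ...]
    orientation_rad: float  # in-plane (xy) long-axis angle
    scale: float = 1.0


@dataclass
class SceneTruth:
    """Complete ground-truth description of a simulated scene."""

    cells: list[CellTruth]
    volume_um: tuple[float, float, float]  # (x, y, z) extent
    mode: str = "2d"  # 2d = monolayer on a single plane; 3d = full volume
    background_components: dict[int, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {r: [(2.0, 510.0, 60.0)] for r in range(6)}
    )
    noise_params: tuple[float, float] | None = (10.0, 0.5)  # (photon scale, read SD)
    psf_sigma_um: float = 0.132  # ~0.5 voxel at the default 0.264 um pitch
    reflection_params: tuple[float, float] = (100.0, 0.6)  # (background, attenuation)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cell_ids in scene truth")
        bg, att = self.reflection_params
        if not (0.0 < att < 1.0):
            raise ValueError("reflection attenuation must be in (0, 1): cells are darker than background")
        if bg <= 0:
            raise ValueError("reflection background must be positive")

    def background_spectrum(self, config: SpectralConfig | None = None) -> np.ndarray:
        return make_signature("background", self.background_components, config).matrix

    def class_names(self) -> list[str]:
        return sorted({c.class_name for c in self.cells})

    def save(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SceneTruth":
        with open(path) as fh:
            d = json.load(fh)
        cells = [
            CellTruth(
                c["cell_id"], c["class_name"], c["shape"],
                tuple(c["center_um"]), tuple(c["size_um"]),
                c["orientation_rad"], c.get("scale", 1.0),
            )
            for c in d.pop("cells")
        ]
        bg = {int(k): [tuple(c) for c in v] for k, v in d.pop("background_components").items()}
        noise = d.pop("noise_params")
        return cls(
            cells=cells,
            volume_um=tuple(d.pop("volume_um")),
            background_components=bg,
            noise_params=tuple(noise) if noise is not None else None,
            reflection_params=tuple(d.pop("reflection_params")),
            **d,
        )


def place_cells(
    n: int,
    shape_spec: ShapeSpec | list[ShapeSpec],
    volume_um: tuple[float, float, float],
    min_gap_um: float,
    seed: int,
    mode: str = "2d",
    max_tries: int = 10_000,
) -> SceneTruth:
    """Place ``n`` non-overlapping cells uniformly in a volume.

    ``min_gap_um`` is the minimum pairwise center-to-center distance.
    With a list of shape specs, classes are assigned round-robin (two
    specs give a 50/50 mixture).  Placement is rejection sampling and
    deterministic given ``seed``; an overcrowded request raises.
    """
    specs = [shape_spec] if isinstance(shape_spec, ShapeSpec) else list(shape_spec)
    if not specs:
        raise ValueError("need at least one shape spec")
    rng = np.random.default_rng(seed)
    vx, vy, vz = volume_um
    cells: list[CellTruth] = []
    centers: list[np.ndarray] = []
    for i in range(n):
        spec = specs[i % len(specs)]
        margin = spec.max_radius_um()
        placed = False
        for _ in range(max_tries):
            x = rng.uniform(margin, vx - margin)
            y = rng.uniform(margin, vy - margin)
            if mode == "2d":
                z = vz / 2.0
            else:
                z = rng.uniform(min(margin, vz / 2.0), max(vz - margin, vz / 2.0))
            p = np.array([x, y, z])
            if all(np.linalg.norm(p - q) >= min_gap_um for q in centers):
                theta = rng.uniform(0.0, np.pi)
                cells.append(
                    CellTruth(i + 1, spec.class_name, spec.shape, (x, y, z),
                              spec.size_um, theta, spec.scale)
                )
                centers.append(p)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n} after {max_tries} tries; "
                "volume too crowded for the requested min_gap"
            )
    return SceneTruth(cells=cells, volume_um=volume_um, mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# rendering


def _cell_mask(cell: CellTruth, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Boolean membership of voxel centers (z, y, x grid) in a cell body."""
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    cx, cy, cz = cell.center_um
    dx, dy, dz = X - cx, Y - cy, Z - cz
    if cell.shape == "sphere":
        r = cell.size_um[0]
        return dx**2 + dy**2 + dz**2 <= r**2
    ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
    # rotate into the cell frame: u along the long axis (in the xy plane)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    if cell.shape == "rod":
        length, r = cell.size_um
        half = max(length / 2.0 - r, 0.0)  # spherocylinder: cylinder + hemispherical caps
        axial = np.clip(u, -half, half)
        return (u - axial) ** 2 + v**2 + dz**2 <= r**2
    a, b, c = cell.size_um  # ellipsoid semi-axes, long axis along u
    return (u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2 <= 1.0


def _grid_coords(n: int, pitch: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pitch


def _apply_noise(arr: np.ndarray, noise_params, rng: np.random.Generator) -> np.ndarray:
    photon_scale, read_sd = noise_params
    out = rng.poisson(np.clip(arr, 0.0, None) * photon_scale) / photon_scale
    out = out + rng.normal(0.0, read_sd, size=arr.shape)
    return np.clip(out, 0.0, None)  # detector output is non-negative


def render_scene(
    truth: SceneTruth, config: SpectralConfig | None = None,
    signatures: dict[str, SpectralSignature] | None = None,
) -> tuple[ReflectionStack, SpectralStack, LabelMap]:
    """Render a scene into reflection + spectral stacks and a truth label map.

    Spectral voxel value = background + sum over cells of
    scale * signature inside the cell, blurred by an isotropic Gaussian
    PSF, then Poisson photon noise and Gaussian read noise (both skipped
    when the corresponding parameter is null).  Reflection voxels hold
    the background level attenuated inside cells (darker than
    background), with the same PSF and noise model.  The label map is
    exact: no blur, no noise.

    Both stacks share one voxel grid (the reflection pitch) so 3D masks
    transfer voxelwise; the spectral z-step is retained in the config as
    acquisition metadata.
    """
    cfg = config or SpectralConfig()
    sigs = signatures if signatures is not None else example_signatures(cfg)
    px, py, pz = cfg.voxel_xyz_reflection_um
    vx, vy, vz = truth.volume_um
    nx, ny = max(int(round(vx / px)), 1), max(int(round(vy / py)), 1)
    nz = 1 if truth.mode == "2d" else max(int(round(vz / pz)), 1)
    xs, ys = _grid_coords(nx, px), _grid_coords(ny, py)
    zs = np.array([vz / 2.0]) if truth.mode == "2d" else _grid_coords(nz, pz)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    class_density: dict[str, np.ndarray] = {}
    for cell in truth.cells:
        if cell.class_name not in sigs:
            raise KeyError(f"no signature for class {cell.class_name!r}")
        mask = _cell_mask(cell, xs, ys, zs)
        labels[(labels == 0) & mask] = cell.cell_id
        dens = class_density.setdefault(cell.class_name, np.zeros((nz, ny, nx)))
        dens[mask] += cell.scale

    bg = truth.background_spectrum(cfg)
    spectral = np.empty((cfg.n_excitations, cfg.n_emission_bins, nz, ny, nx))
    spectral[:] = bg[:, :, None, None, None]
    for name, dens in class_density.items():
        spectral += sigs[name].matrix[:, :, None, None, None] * dens[None, None]

    refl_bg, attenuation = truth.reflection_params
    any_cell = labels > 0
    reflection = np.full((nz, ny, nx), refl_bg)
    reflection[any_cell] *= attenuation

    if truth.psf_sigma_um and truth.psf_sigma_um > 0:
        sig_vox = [truth.psf_sigma_um / p for p in (pz, py, px)]
        if nz == 1:
            sig_vox[0] = 0.0
        reflection = ndimage.gaussian_filter(reflection, sig_vox)
        for r in range(cfg.n_excitations):
            for c in range(cfg.n_emission_bins):
                spectral[r, c] = ndimage.gaussian_filter(spectral[r, c], sig_vox)

    if truth.noise_params is not None:
        rng = np.random.default_rng(truth.seed)
        spectral = _apply_noise(spectral, truth.noise_params, rng)
        reflection = _apply_noise(reflection, truth.noise_params, rng)

    return (
        ReflectionStack(reflection, cfg),
        SpectralStack(spectral, cfg),
        LabelMap(labels if nz > 1 else labels[0], mode=truth.mode.upper(), params=None),
    )


# ---------------------------------------------------------------------------
# fast catalog sampling (bypasses rendering for ML-scale populations)


def sample_catalog(
    signature: SpectralSignature,
    n: int,
    cv: float,
    seed: int,
    config: SpectralConfig | None = None,
) -> "HyperspectrumCatalog":
    """Draw ``n`` hyperspectra around a class signature.

    Each entry is the signature matrix times entrywise multiplicative
    lognormal noise with mean 1 and coefficient of variation ``cv``,
    emulating the minor within-population variability of real single
    cells.  Deterministic given ``seed``.
    """
    from .catalog import Hyperspectrum, HyperspectrumCatalog

    if n <= 0:
        raise ValueError("n must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    cfg = config or SpectralConfig()
    rng = np.random.default_rng(seed)
    if cv == 0:
        factors = np.ones((n, 6, 32))
    else:
        sigma2 = np.log1p(cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=(n, 6, 32))
    entries = [
        Hyperspectrum(i + 1, signature.matrix * factors[i], (0.0, 0.0), source="2D")
        for i in range(n)
    ]
    labels = [signature.class_name] * n
    return HyperspectrumCatalog(
        entries, labels, cfg,
        provenance={"generator": "sample_catalog", "seed": seed, "cv": cv},
    )
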