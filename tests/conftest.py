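import numpy as np
import pytest

import crif


@pytest.fixture(scope="session")
def cfg():
    return crif.SpectralConfig()


@pytest.fixture(scope="session")
def signatures(cfg):
    return crif.example_signatures(cfg)


@pytest.fixture(scope="session")
def two_class_catalogs(cfg, signatures):
    """300 sampled cells per class for two well-separated species."""
    a = crif.sample_catalog(signatures["pseudomonas_like"], 300, cv=0.1, seed=11, config=cfg)
    b = crif.sample_catalog(signatures["paenibacillus_like"], 300, cv=0.1, seed=12, config=cfg)
    return a, b


@pytest.fixture(scope="session")
def clean_monolayer(cfg, signatures):
    """10 well-separated rods on one plane, noise and PSF off."""
    truth = crif.place_cells(
        10, crif.ShapeSpec("pseudomonas_like", "rod", (2.5, 0.5)),
        (30.0, 30.0, 2.0), min_gap_um=4.0, seed=7, mode="2d",
    )
    truth.noise_params = None
    truth.psf_sigma_um = 0.0
    reflection, spectral, labels = crif.render_scene(truth, cfg, signatures)
    return truth, reflection, spectral, labels


@pytest.fixture(scope="session")
def noisy_monolayer(cfg, signatures):
    """10 well-separated rods with the default noise and PSF."""
    truth = crif.place_cells(
        10, crif.ShapeSpec("pseudomonas_like", "rod", (2.5, 0.5)),
        (30.0, 30.0, 2.0), min_gap_um=4.0, seed=5, mode="2d",
    )
    reflection, spectral, labels = crif.render_scene(truth, cfg, signatures)
    return truth, reflection, spectral, labels
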