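"""Shared fixtures: small atlases, cohorts, and trained desk-scale models.

Expensive fixtures are session-scoped so the whole suite trains only a
handful of small VAEs.
"""

import numpy as np
import pytest

from tautraj import (CohortConfig, VAEConfig, build_phantom_atlas,
                     generate_cohort, normalize_intensity, train_vae)


@pytest.fixture(scope="session")
def small_atlas():
    """32^3 atlas with one bilateral region per Braak group."""
    return build_phantom_atlas((32, 32, 32), n_regions_per_group=1, seed=0)


@pytest.fixture(scope="session")
def two_region_atlas():
    """32^3 atlas with two bilateral regions per Braak group (study layout)."""
    return build_phantom_atlas((32, 32, 32), n_regions_per_group=2, seed=7)


@pytest.fixture(scope="session")
def clean_cohort(small_atlas):
    """Small noiseless cohort: deterministic volumes, no nuisance."""
    cfg = CohortConfig(n=24, noise_sd=0.0, scale_sd=0.0, smoothing_fwhm_vox=0.0,
                       atypical_fraction=0.0)
    return generate_cohort(small_atlas, cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_cohort(small_atlas):
    """Default-nuisance cohort at reduced size for fast downstream tests."""
    return generate_cohort(small_atlas, CohortConfig(n=48), seed=5)


@pytest.fixture(scope="session")
def tiny_vae_setup():
    """20 tiny synthetic volumes (16^3) plus a desk VAE config."""
    atlas = build_phantom_atlas((16, 16, 16), n_regions_per_group=1, seed=3)
    cfg = CohortConfig(n=20, noise_sd=0.02, scale_sd=0.05,
                       smoothing_fwhm_vox=1.0, atypical_fraction=0.0)
    cohort = generate_cohort(atlas, cfg, seed=21)
    volumes = [normalize_intensity(v, atlas) for v in cohort.volumes]
    vcfg = VAEConfig(n_conv_layers=2, latent_dim=4, base_channels=4,
                     epochs=80, batch_size=8, learning_rate=3e-3, seed=0)
    return atlas, cohort, volumes, vcfg


@pytest.fixture(scope="session")
def tiny_trained(tiny_vae_setup):
    atlas, cohort, volumes, vcfg = tiny_vae_setup
    return atlas, cohort, volumes, vcfg, train_vae(volumes, vcfg)
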