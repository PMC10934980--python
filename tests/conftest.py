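"""Shared fixtures.

The heavyweight fixtures (a synthetic dataset and a tiny trained
diffusion model) are session-scoped so the colorization / evaluation
tests and the acceptance suite all share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirseed as ns
from nirseed import ddpm

DATASET_SEED = 7
TRAIN_STEPS = 6000


@pytest.fixture(scope="session")
def dataset():
    """Unpaired synthetic split: 256 RGB + 256 NIR train scenes, 16 eval pairs."""
    return ns.make_dataset(256, 16, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def desk_cfg():
    return ns.desk_config(train_steps=TRAIN_STEPS, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def trained(dataset, desk_cfg):
    """Checkpoint of the 16x16 desk-scale model trained on the RGB split."""
    return ddpm.train(desk_cfg, dataset.train_rgb)


@pytest.fixture(scope="session")
def trained_model(trained):
    return trained.build_model()


@pytest.fixture(scope="session")
def desk_schedule(desk_cfg):
    return ddpm.schedule_for(desk_cfg)


@pytest.fixture(scope="session")
def seeded_run(trained_model, desk_schedule, dataset):
    """Lazily cached high-pass seeding runs over the eval NIR batch, one
    reverse chain per (sigma, seed) — shared across the σ-dependent tests."""
    from nirseed.iterative_seeding import HighpassTranslator, iterative_seeding

    refs = np.stack([p.nir for p in dataset.eval_pairs])
    cache: dict[tuple[float, int], np.ndarray] = {}

    def get(sigma: float, seed: int = 17) -> np.ndarray:
        key = (float(sigma), seed)
        if key not in cache:
            cache[key] = iterative_seeding(
                trained_model, refs, HighpassTranslator(sigma), desk_schedule, seed=seed
            )
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
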