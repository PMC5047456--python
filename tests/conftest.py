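"""Shared fixtures: phantoms and studies are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import craniofield as cf


@pytest.fixture(scope="session")
def default_spec():
    return cf.HeadPhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default superficial-tumor phantom at standard resolution."""
    return cf.build_head_phantom(default_spec)


@pytest.fixture(scope="session")
def study():
    """Study on the default phantom: mesh + tensors + slope + electrodes."""
    return cf.experiments.PhantomStudy(seed=1)


@pytest.fixture(scope="session")
def baseline(study):
    """Intact-skull solve of both pairs."""
    return study.run(None, name="intact")


@pytest.fixture(scope="session")
def cran50(study):
    """50-mm craniectomy over the tumor, both pairs."""
    return study.run(cf.SkullDefectSpec(kind="circle", diameter=50.0),
                     name="circle50")


@pytest.fixture(scope="session")
def sweep_table(study):
    """Full craniectomy diameter sweep (10-100 mm, step 5) for the L/R pair."""
    return cf.diameter_sweep(study, diameters=list(range(10, 101, 5)),
                             pairs=("LR",))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


def random_spd(rng, scale=1.0):
    """Random symmetric positive-definite 3x3 tensor."""
    A = rng.normal(size=(3, 3))
    return scale * (A @ A.T + 0.5 * np.eye(3))
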