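"""Shared fixtures: small phantom cohorts and one full demo run.

The end-to-end demo (20 train / 10 test at 48 cubed) is expensive, so it
runs once per session and its model, report and held-out subjects are
reused by every test that needs a trained pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lesionsynth.normalise import normalise_bundle
from lesionsynth.phantom import PhantomParams, generate_cohort, generate_subject
from lesionsynth.pipeline import run_demo


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """32-cubed phantom parameters used by component-level tests."""
    return PhantomParams(shape=(32, 32, 32), seed=7, lesion_radius_range=(2.0, 2.5))


@pytest.fixture(scope="session")
def small_train_cohort(small_params):
    """Six healthy, normalised 32-cubed subjects."""
    return [normalise_bundle(b) for b in generate_cohort(6, small_params, healthy=True)]


@pytest.fixture(scope="session")
def small_lesion_subject(small_params):
    """One lesioned, normalised 32-cubed subject on the same lattice."""
    p = dataclasses.replace(small_params, seed=4242)
    return normalise_bundle(generate_cohort(1, p, healthy=False)[0])


@pytest.fixture(scope="session")
def demo():
    """Full end-to-end study: 20 healthy train, 10 lesioned test, 48^3."""
    return run_demo(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170908)
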