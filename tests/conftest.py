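"""Shared fixtures: phantoms, truth-derived label/relaxation maps."""

from __future__ import annotations

import numpy as np
import pytest

from discqmri.phantom import FissureSpec, PhantomSpec, PhantomTruth, make_phantom
from discqmri.relaxometry import RelaxationMap
from discqmri.segmentation import DiscLabelMap


@pytest.fixture(scope="session")
def intact_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def fissured_spec() -> PhantomSpec:
    return PhantomSpec(fissure=FissureSpec())


@pytest.fixture(scope="session")
def intact_truth(intact_spec) -> PhantomTruth:
    return make_phantom(intact_spec)


@pytest.fixture(scope="session")
def fissured_truth(fissured_spec) -> PhantomTruth:
    return make_phantom(fissured_spec)


def truth_labelmap(truth: PhantomTruth) -> DiscLabelMap:
    """Ground-truth labels wrapped as a segmentation label map."""
    return DiscLabelMap(labels=truth.labels.copy(), pixel_spacing=truth.pixel_spacing)


def maps_from_truth(truth: PhantomTruth) -> tuple[RelaxationMap, RelaxationMap]:
    """Noise-free relaxation maps holding the exact ground-truth values."""
    valid = truth.pd > 0
    zeros = np.zeros_like(truth.t1)
    t1 = RelaxationMap(values=np.where(valid, truth.t1, np.nan), amplitude=np.ones_like(zeros),
                       rss=zeros, valid_mask=valid, kind="T1",
                       pixel_spacing=truth.pixel_spacing, bounds=(1.0, 5000.0))
    t2 = RelaxationMap(values=np.where(valid, truth.t2, np.nan), amplitude=np.ones_like(zeros),
                       rss=zeros, valid_mask=valid, kind="T2",
                       pixel_spacing=truth.pixel_spacing, bounds=(1.0, 1000.0))
    return t1, t2


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / max(a.sum() + b.sum(), 1)
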