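"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from clonoprev.ddpcr import AssayConstants
from clonoprev.signatures import ExposureVector, SignatureProfile


@pytest.fixture
def study_constants() -> AssayConstants:
    """QX200 constants with a 5 ul input volume."""
    return AssayConstants(input_volume=5.0)


def eps_graph_components(points: np.ndarray, eps: float) -> np.ndarray:
    """Brute-force oracle: connected components of the eps-neighbourhood
    graph (boundary inclusive), independent of any clustering library."""
    d = cdist(points, points)
    _, labels = connected_components(csr_matrix(d <= eps), directed=False)
    return labels


def partition_signature(labels) -> set[frozenset[int]]:
    """Canonical form of a point partition: set of index-sets, noise (-1)
    as singletons."""
    groups: dict[int, set[int]] = {}
    singletons = []
    for i, lab in enumerate(labels):
        if lab == -1:
            singletons.append(frozenset([i]))
        else:
            groups.setdefault(int(lab), set()).add(i)
    return {frozenset(g) for g in groups.values()} | set(singletons)


def make_peaked_profile(signature_id: str, peak_channel: int,
                        peak_mass: float = 0.9) -> SignatureProfile:
    """A synthetic signature concentrated on one channel."""
    probs = np.full(96, (1.0 - peak_mass) / 95)
    probs[peak_channel] = peak_mass
    return SignatureProfile(signature_id, probs)


@pytest.fixture
def toy_catalog() -> dict[str, SignatureProfile]:
    """Three well-separated synthetic signatures (smoking-labelled SBS4
    plus two ageing-labelled ones)."""
    return {
        "SBS4": make_peaked_profile("SBS4", 10),
        "SBS5": make_peaked_profile("SBS5", 50),
        "SBS1": make_peaked_profile("SBS1", 90),
    }


@pytest.fixture
def toy_exposures() -> ExposureVector:
    return ExposureVector("PT01", {"SBS4": 200.0, "SBS5": 100.0, "SBS1": 100.0})
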