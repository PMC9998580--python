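"""Shared fixtures: small synthetic panels and a fixed PSD toy kinship."""

import numpy as np
import pytest

from gsopt import (
    MarkerMatrix,
    PopSimConfig,
    RelationshipMatrix,
    compute_grm,
    simulate_population,
)

SIX_IDS = [f"g{i}" for i in range(1, 7)]


@pytest.fixture(scope="session")
def toy_kinship() -> RelationshipMatrix:
    """A fixed 6-genotype PSD relationship matrix used across criterion tests."""
    rng = np.random.default_rng(42)
    l = rng.normal(size=(6, 6))
    values = l @ l.T / 6 + 0.5 * np.eye(6)
    return RelationshipMatrix(SIX_IDS, values)


@pytest.fixture(scope="session")
def small_structured_panel() -> tuple[MarkerMatrix, np.ndarray]:
    """n=60, m=300, 2 subpopulations at intermediate divergence."""
    return simulate_population(PopSimConfig(n=60, m=300, k_subpops=2, fst=0.2, rng_seed=7))


@pytest.fixture(scope="session")
def small_unstructured_panel() -> MarkerMatrix:
    markers, _ = simulate_population(PopSimConfig(n=50, m=300, k_subpops=1, fst=0.0, rng_seed=2))
    return markers


@pytest.fixture(scope="session")
def small_grm(small_unstructured_panel) -> RelationshipMatrix:
    return compute_grm(small_unstructured_panel)


def random_psd_kinship(rng: np.random.Generator, n: int = 6) -> RelationshipMatrix:
    l = rng.normal(size=(n, n))
    values = l @ l.T / n + 0.5 * np.eye(n)
    return RelationshipMatrix([f"s{i}" for i in range(n)], values)
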