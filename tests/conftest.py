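"""Shared fixtures.

The expensive objects (the simulated recovery fixture and its fitted model)
are session-scoped so the recovery, amplitude, and stage tests all reuse a
single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from sinucell import (
    CircularSimSpec,
    ModelConfig,
    fit,
    pseudotime,
    simulate_circular,
    standardize_genes,
)
from sinucell.preprocessing import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """A tiny counts matrix with a mitochondrial gene column."""
    values = np.array(
        [
            [0.0, 3.0, 10.0, 1.0],
            [2.0, 5.0, 40.0, 0.0],
            [1.0, 0.0, 2.0, 9.0],
        ]
    )
    return ExpressionMatrix(
        values=values,
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["GA", "GB", "GC", "MT-ND1"],
        scale="counts",
    )


@pytest.fixture(scope="session")
def recovery_fixture():
    """Cells on a noisy circular trajectory: 500 cells, 200 genes (150
    periodic with amplitudes U(0.5, 2)), Gaussian noise sd 0.3, uniform
    pseudo-time, stage arcs of width (π, π/2, π/2)."""
    spec = CircularSimSpec(
        n_cells=500,
        n_genes=200,
        n_periodic_genes=150,
        amplitude_range=(0.5, 2.0),
        noise_sd=0.3,
        pseudotime_distribution="uniform",
        seed=0,
    )
    matrix, truth = simulate_circular(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def recovery_model(recovery_fixture):
    """Default-config fit of the recovery fixture plus inferred pseudo-times."""
    _, matrix, truth = recovery_fixture
    standardized = standardize_genes(matrix)
    model = fit(standardized, ModelConfig(seed=0))
    result = pseudotime(model, standardized)
    return standardized, model, result, truth


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Evenly spaced cells on a noise-free circle; the standardized columns
    are exactly sinusoidal, so a perfect reconstruction exists."""
    spec = CircularSimSpec(
        n_cells=100,
        n_genes=20,
        n_periodic_genes=20,
        amplitude_range=(0.5, 2.0),
        noise_sd=0.0,
        pseudotime_distribution="grid",
        seed=3,
    )
    matrix, truth = simulate_circular(spec)
    return standardize_genes(matrix), truth
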