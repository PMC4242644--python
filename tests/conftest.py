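"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from coexmotif.expression import ExpressionMatrix
from coexmotif.synthetic import (
    SimulationConfig,
    generate_expression,
    generate_motif_library,
    generate_promoters,
    generate_regulatory_structure,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=80,
        n_tfs=4,
        module_size=10,
        n_samples=48,
        coupling=1.0,
        noise_sd=0.5,
        missing_rate=0.0,
        motif_width_range=(10, 12),
        library_redundancy=3,
        consensus_strength=0.95,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Motif library, regulatory structure, genome and expression for one seed."""
    motifs, clusters = generate_motif_library(
        small_config.n_tfs,
        small_config.library_redundancy,
        small_config.motif_width_range,
        small_config.background,
        small_config.seed,
        small_config.consensus_strength,
    )
    gt = generate_regulatory_structure(small_config, sorted(clusters))
    gt.planted_motifs = {tf: f"{base}v0" for tf, base in gt.planted_motifs.items()}
    genome, features, promoters = generate_promoters(gt, small_config, motifs)
    expr = generate_expression(gt, small_config)
    return {
        "config": small_config,
        "motifs": motifs,
        "clusters": clusters,
        "gt": gt,
        "genome": genome,
        "features": features,
        "promoters": promoters,
        "expression": expr,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matrix(values: np.ndarray, observed: np.ndarray | None = None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    if observed is None:
        observed = np.ones_like(values, dtype=bool)
    vals = values.copy()
    vals[~observed] = np.nan
    return ExpressionMatrix(
        [f"g{i:03d}" for i in range(g)],
        [f"s{j:03d}" for j in range(s)],
        vals,
        observed,
    )
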