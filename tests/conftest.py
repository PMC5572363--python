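import numpy as np
import pytest

from cosegmap import (
    GenotypeMatrix,
    SimConfig,
    build_skeleton,
    clusters_from_truth,
    find_clusters,
    segregation_filter,
    simulate_dh_population,
)


def matrix_from_strings(rows: dict[str, str]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from marker -> call-string (A/B/U), lines auto-named."""
    markers = list(rows)
    n = len(next(iter(rows.values())))
    code = {"A": 0, "B": 1, "U": -1}
    calls = np.array(
        [[code[c] for c in rows[m]] for m in markers], dtype=np.int8
    ).T
    lines = [f"l{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(lines, markers, calls)


@pytest.fixture(scope="session")
def clean_lg():
    """Error-free single LG: 11 loci spaced 10 cM, 85% co-segregation, n=177."""
    pos = np.arange(11) * 10.0
    cfg = SimConfig(
        n_lines=177, n_lg=1, lg_length_cM=100.0, locus_positions=[pos],
        coseg_proportion=0.85, miscall_rate=0.0, missing_rate=0.0, seed=11,
    )
    matrix, truth = simulate_dh_population(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def noisy_lg():
    """Single LG with 1% miscalls and 2% missing: 13 loci spaced 5 cM, n=200."""
    pos = np.arange(13) * 5.0
    cfg = SimConfig(
        n_lines=200, n_lg=1, lg_length_cM=60.0, locus_positions=[pos],
        coseg_proportion=0.8, miscall_rate=0.01, missing_rate=0.02, seed=42,
    )
    matrix, truth = simulate_dh_population(cfg)
    filtered, _ = segregation_filter(matrix)
    return cfg, filtered, truth


@pytest.fixture(scope="session")
def clean_lg_experiment(clean_lg):
    """Clusters + skeleton of the error-free LG (detected clusters)."""
    _, matrix, _ = clean_lg
    clusters = find_clusters(matrix, list(matrix.markers), lg_id="LG01", rng=0)
    skeleton_map = build_skeleton(matrix, clusters, fn="haldane")
    return matrix, clusters, skeleton_map


@pytest.fixture(scope="session")
def noisy_lg_experiment(noisy_lg):
    """Truth clusters + skeleton of the noisy LG."""
    _, matrix, truth = noisy_lg
    clusters = clusters_from_truth(matrix, truth, "LG01", rng=0)
    skeleton_map = build_skeleton(matrix, clusters, fn="haldane")
    return matrix, clusters, skeleton_map
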