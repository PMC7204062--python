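import numpy as np
import pandas as pd
import pytest

from rindqtl import simulate as sim
from rindqtl.mapqc import MarkerMatrix


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(
        n_lines=200,
        chromosomes=(sim.ChromosomeSpec(100.0, 100_000_000, 51),) * 2,
        seed=5,
        qtl=(sim.QTLSpec(1, 50.0, tuple([0.3] * 7)),),
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    gmap = sim.simulate_genetic_map(small_config)
    pop, arch = sim.simulate_ril_population(gmap, small_config.n_lines, seed=5)
    table = sim.simulate_phenotypes(pop, arch, small_config)
    return gmap, pop, arch, table


@pytest.fixture(scope="session")
def small_marker_matrix(small_population):
    gmap, pop, _, _ = small_population
    return MarkerMatrix(pop.geno, gmap[["marker", "chrom", "pos_bp"]])


def balanced_table(y: np.ndarray, lines=None, envs=None) -> pd.DataFrame:
    """Long-format table from a (lines, envs, reps) array."""
    n, e, r = y.shape
    lines = lines or [f"L{i}" for i in range(n)]
    envs = envs or [f"E{j + 1}" for j in range(e)]
    rows = [
        {"line": lines[i], "env": envs[j], "rep": k + 1, "value": y[i, j, k]}
        for i in range(n)
        for j in range(e)
        for k in range(r)
    ]
    return pd.DataFrame(rows)
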