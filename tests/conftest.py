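import numpy as np
import pandas as pd
import pytest

from triheme import (
    CellTable,
    GeneCountMatrix,
    SimConfig,
    aggregate_to_genes,
    log_normalize,
    plant_qc_violations,
    simulate,
)


def two_population_config(**overrides) -> SimConfig:
    """A generator configuration with no planted genes unless requested."""
    base = dict(
        n_cells={"HE_AGM": 100, "HE_YSP": 100},
        n_genes=1000,
        depth_mean=100.0,
        n_he_restricted=0,
        n_endothelial_biased=0,
        n_hematopoietic_biased=0,
        n_emp_fate=0,
        n_lmp_fate=0,
        n_interhe_up=0,
        n_entropy_shift=0,
        n_switch=0,
        n_batch_genes=0,
        n_factors=10,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_sim():
    """Full 9-population dataset under the package's default study conditions."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def planted_qc_sim(default_sim):
    return plant_qc_violations(default_sim, n_low_genes=5, n_high_mito=5,
                               n_high_hb=5, n_replicates=3, seed=2)


@pytest.fixture(scope="session")
def norm_gcm(default_sim):
    return log_normalize(aggregate_to_genes(default_sim.icm, default_sim.gene_model))


def make_gcm(values: dict, populations: dict, normalized: bool = True):
    """Construct a (GeneCountMatrix, CellTable) pair from per-population
    per-gene count vectors: values[gene][population] -> list of counts.

    The normalized layer is set to the counts themselves (tests control the
    scale directly).
    """
    pops = list(populations)
    cell_ids = [f"{p}_{i}" for p in pops for i in range(populations[p])]
    genes = list(values)
    counts = np.zeros((len(cell_ids), len(genes)))
    for j, g in enumerate(genes):
        col = []
        for p in pops:
            col.extend(values[g][p])
        counts[:, j] = col
    gcm = GeneCountMatrix(cell_ids, genes, counts, counts.copy() if normalized else None)
    cells = CellTable(pd.DataFrame(
        {"population": [p for p in pops for _ in range(populations[p])]},
        index=pd.Index(cell_ids, name="cell_id"),
    ))
    return gcm, cells
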