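import numpy as np
import pandas as pd
import pytest

import pulsekinetics as pk


@pytest.fixture(scope="session")
def small_geometry() -> pk.SegmentationSet:
    """Four ellipsoid cells with nuclei on a 64x64x16 grid."""
    grid = pk.VoxelGrid((64, 64, 16))
    return pk.synth.make_cell_geometry(grid, 4, seed=0)


@pytest.fixture(scope="session")
def small_fields(small_geometry):
    return pk.subcellular.distance_fields(small_geometry)


@pytest.fixture(scope="session")
def small_experiment(small_geometry, small_fields):
    """A small but complete pulse-chase run with ground truth."""
    truths = pk.synth.random_gene_truths(8, seed=1, n_reference=2)
    cfg = pk.SimConfig(n_cells=4, genes=truths, detection_efficiency=1.0, seed=7)
    reads, truth = pk.synth.simulate_experiment(cfg, small_geometry, fields=small_fields)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def small_matrix(small_geometry, small_fields, small_experiment):
    cfg, reads, _ = small_experiment
    assigned = pk.subcellular.assign_and_partition(
        reads, small_geometry, fields=small_fields
    )
    design = pk.PulseChaseDesign()
    cm = pk.subcellular.count_matrix(assigned, small_geometry, design=design)
    return cm, assigned, design


@pytest.fixture
def toy_reads() -> pd.DataFrame:
    df = pk.datamodel.empty_reads()
    rows = pd.DataFrame(
        {
            "gene": ["A", "B", "A"],
            "x": [1, 2, 3],
            "y": [1, 2, 3],
            "z": [0, 1, 2],
            "timepoint_h": [0.0, 2.0, 6.0],
            "cell_id": [1, 1, 2],
            "compartment": ["nucleus", "middle", "periphery"],
            "dr": [np.nan, 0.4, 0.95],
            "quality": [0.1, np.nan, 0.2],
        }
    )
    return pd.concat([df, rows], ignore_index=True)
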