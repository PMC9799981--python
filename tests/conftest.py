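import numpy as np
import pandas as pd
import pytest

from ireskit import (
    LfqMatrix,
    SimImageConfig,
    SimLfqConfig,
    simulate_images,
    simulate_lfq,
)


@pytest.fixture(scope="session")
def small_field():
    """One small 2D field with moderate spot density and known truth."""
    cfg = SimImageConfig(
        n_fields=1,
        image_shape=(200, 200),
        n_nuclei_per_field=5,
        nucleus_radius=16.0,
        spots_per_cell_rate={"Cy3": 3.0, "Cy5": 2.0},
        coloc_fraction=0.5,
        seed=11,
    )
    stacks, truth = simulate_images(cfg)
    return cfg, stacks[0], truth


@pytest.fixture(scope="session")
def lfq_sim():
    """Small label-free dataset with two spiked enrichments."""
    from ireskit import Spike

    cfg = SimLfqConfig(
        n_proteins=200,
        seed=5,
        spiked=(
            Spike("P00003", "nucleus_hypoxia_vs_normoxia", 2.0),
            Spike("P00007", "cytoplasm_hypoxia_vs_normoxia", -2.0),
        ),
    )
    return cfg, simulate_lfq(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-protein, 2-run raw matrix for arithmetic oracles."""
    intensities = pd.DataFrame(
        {"r1": [10.0, 20.0, np.nan], "r2": [40.0, np.nan, 60.0]},
        index=["A", "B", "C"],
    )
    annotation = pd.DataFrame(
        {
            "condition": ["normoxia", "hypoxia"],
            "compartment": ["nucleus", "nucleus"],
            "bio_rep": ["b1", "b1"],
            "tech_rep": [1, 1],
        },
        index=pd.Index(["r1", "r2"], name="run"),
    )
    return LfqMatrix(intensities, annotation)
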