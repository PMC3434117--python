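import numpy as np
import pandas as pd
import pytest

from twostage_rp import array_io, synthetic


@pytest.fixture
def toy_design() -> array_io.DesignTable:
    return array_io.DesignTable(
        {
            "A1": ("LPS", "NS"),
            "A2": ("LPS", "NS"),
            "A3": ("NS", "LPS"),  # dye-swapped
        }
    )


def spot_rows(array_id, gene_id, rep, fg5, bg5, fg3, bg3):
    return {
        "array_id": array_id,
        "gene_id": gene_id,
        "replicate": rep,
        "fg_cy5": fg5,
        "bg_cy5": bg5,
        "fg_cy3": fg3,
        "bg_cy3": bg3,
    }


@pytest.fixture
def toy_spots(toy_design) -> pd.DataFrame:
    """2 genes x 2 replicates on each of the 3 design arrays, clean values."""
    rows = []
    rng = np.random.default_rng(42)
    for a in toy_design.arrays:
        for g in ("g1", "g2"):
            for rep in (1, 2):
                base = 100 if g == "g1" else 400
                rows.append(
                    spot_rows(
                        a, g, rep,
                        base + rng.integers(0, 20), 20,
                        base / 2 + rng.integers(0, 20), 20,
                    )
                )
    return pd.DataFrame(rows)


@pytest.fixture
def small_experiment():
    """A 300-gene simulated experiment shared across tests (cheap)."""
    cfg = synthetic.SimulationConfig(
        n_genes=300, de_fraction=0.1, seed=123, nonpositive_fraction=0.0
    )
    spots, design, truth = synthetic.simulate_experiment(cfg)
    return cfg, spots, design, truth
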