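import numpy as np
import pandas as pd
import pytest

from hscfate import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_transplant():
    config = sim.TransplantSimConfig(n_mice_per_group=6, seed=11)
    pb, truth = sim.simulate_transplants(config)
    return pb, truth


@pytest.fixture(scope="session")
def null_atac():
    """5 vs 5 samples, no planted effects."""
    config = sim.AtacSimConfig(
        n_regions=500, groups=(("X", "J"), ("X", "O")), seed=5
    )
    return sim.simulate_atac(config)


@pytest.fixture(scope="session")
def planted_atac():
    config = sim.AtacSimConfig(
        n_regions=1000,
        groups=(("X", "J"), ("X", "O")),
        planted_sets=(
            sim.PlantedSet("gain", 60, {"X:O": 2.0},
                           motif_id="MOTIF_GATA", motif_prob=1.0),
            sim.PlantedSet("loss", 60, {"X:O": -2.0}),
        ),
        seed=7,
    )
    return sim.simulate_atac(config)


@pytest.fixture(scope="session")
def sc_data():
    config = sim.ScSimConfig(
        n_cells_per_group=120,
        n_genes=800,
        fail_fraction=0.1,
        signature_sets=(
            sim.SignatureSet("prolif", tuple(range(30)), {"CD49b-": 0.5}),
        ),
        seed=13,
    )
    return sim.simulate_cells(config)


@pytest.fixture()
def toy_pb():
    """Hand-built PB table for one clearly myeloid-biased, reconstituted mouse."""
    rows = []
    for t, lineage, donor, total in [
        (2, "leukocyte_total", 400, 80000),
        (2, "platelet", 100, 20000),
        (6, "leukocyte_total", 500, 80000),
        (6, "B", 40, 20000),
        (6, "T", 20, 20000),
        (6, "NK", 5, 20000),
        (6, "myeloid", 435, 20000),
    ]:
        rows.append({"mouse_id": "m1", "group": "J:CD49b-",
                     "timepoint_months": t, "compartment": "PB",
                     "lineage": lineage, "donor_events": donor,
                     "total_events": total})
    return pd.DataFrame(rows)
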