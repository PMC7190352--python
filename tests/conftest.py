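import numpy as np
import pandas as pd
import pytest

from explantquant import (
    ProjectionFrame,
    QuantConfig,
    SyntheticNucleiConfig,
    generate_nuclei,
    measure_sample,
)


@pytest.fixture(scope="session")
def default_quant_config():
    return QuantConfig()


@pytest.fixture(scope="session")
def explant_sample():
    """One wildtype-like synthetic explant, projected and measured."""
    cfg = SyntheticNucleiConfig(sample_kind="explant", n_nuclei=800, seed=11)
    tbl, refs = generate_nuclei(cfg)
    frame = ProjectionFrame.from_axis((0.0, 0.0, 1.0))
    proj, refs_2d = measure_sample(tbl, refs, frame, cfg.cell_diameter)
    return cfg, tbl, refs, proj, refs_2d


@pytest.fixture
def toy_filter_tables():
    """Eight nuclei: 2 EVL, 1 dividing, 1 outside the 100 µm depth window,
    1 beyond 150 µm from the reference, 3 clean."""
    tbl = pd.DataFrame(
        {
            "sample_id": "toy",
            "nucleus_id": np.arange(8),
            "x_um": 0.0,
            "y_um": 0.0,
            "z_um": [0.0, 10.0, 20.0, 0.0, 40.0, 50.0, 130.0, 60.0],
            "ch_signal_mean": 50.0,
            "ch_dapi_mean": 200.0,
            "is_evl": [True, True, False, False, False, False, False, False],
            "is_dividing": [False, False, True, False, False, False, False, False],
        }
    )
    proj = pd.DataFrame(
        {
            "nucleus_id": np.arange(8),
            "u_um": 0.0,
            "v_um": 0.0,
            "dist_to_ref_um": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 160.0],
            "tier": 0.0,
        }
    )
    return tbl, proj
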