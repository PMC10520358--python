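import numpy as np
import pandas as pd
import pytest

from pillarscreen import build_region_map, load_drug_panel, pillar_chip_layout


@pytest.fixture(scope="session")
def layout():
    return pillar_chip_layout()


@pytest.fixture(scope="session")
def region_map(layout):
    return build_region_map(layout)


@pytest.fixture(scope="session")
def panel():
    return load_drug_panel()


@pytest.fixture()
def planted_panel():
    """Small screen with three strongly 3D-sensitive drugs planted.

    17 background drugs follow the usual resistant shift (3D = 2D + 55);
    drugs 5, 11 and 17 are planted with mid-range 2D viability but very
    low 3D viability — 3D-specific kill — putting them far past the hit
    thresholds while the background stays far inside.  All values are
    whole percents so that areas are integral at a base area of 100 px.
    """
    n = 20
    rv2d = np.round(np.linspace(5, 95, n))
    rv3d = rv2d + 55.0
    planted = [5, 11, 17]  # 1-based drug ids
    for d in planted:
        rv2d[d - 1] = 50.0
        rv3d[d - 1] = 5.0
    effects = pd.DataFrame(
        {"drug_id": np.arange(1, n + 1), "rv2d_true": rv2d, "rv3d_true": rv3d}
    )
    return effects, planted
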