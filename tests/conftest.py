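import numpy as np
import pytest

from misosip.provenance import load_pathway, propagate
from misosip.tables import frame_from_fractions


@pytest.fixture(scope="session")
def nucleotide_result():
    return propagate(load_pathway("nucleotide_biosynthesis"))


@pytest.fixture(scope="session")
def lipid_result():
    return propagate(load_pathway("lipid_biosynthesis"))


@pytest.fixture()
def srz_like_frame():
    """Replicate table shaped like a harvest row of a 13C-DIC slurry run:
    DIC at F ~ 0.836, CH4 at F ~ 0.096, methanol at natural abundance."""
    rows = []
    rng = np.random.default_rng(42)
    for rep in (1, 2, 3):
        for pool, f in (("DIC", 0.836), ("CH4", 0.0960), ("MEOH", 0.0110564)):
            rows.append({
                "pool": pool, "replicate": rep, "time_days": 43.0,
                "fraction_13c": f + rng.normal(0, 2e-5), "sd": 0.5,
            })
    return frame_from_fractions("srz-like", rows)
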