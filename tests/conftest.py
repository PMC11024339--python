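import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrlink.harmonize import HarmonizedSet

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_h(bx, by, sx=None, sy=None, exposure_id="exp", outcome_id="out"):
    """Build a HarmonizedSet straight from effect arrays (test shortcut)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.asarray(sx, float) if sx is not None else np.full_like(bx, 0.01)
    sy = np.asarray(sy, float) if sy is not None else np.full_like(bx, 0.01)
    pairs = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(bx))],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf_exp": 0.3, "eaf_out": 0.3, "action": "kept_as_is",
    })
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id,
                         pairs=pairs)


def tables_to_harmonized(exposure, outcome):
    """Join simulated exposure/outcome tables on rsid without any filtering."""
    e, o = exposure.data, outcome.data.set_index("rsid")
    o = o.loc[e["rsid"]]
    pairs = pd.DataFrame({
        "rsid": e["rsid"].to_numpy(),
        "beta_exp": e["beta"].to_numpy(), "se_exp": e["se"].to_numpy(),
        "beta_out": o["beta"].to_numpy(), "se_out": o["se"].to_numpy(),
        "eaf_exp": e["eaf"].to_numpy(), "eaf_out": o["eaf"].to_numpy(),
        "action": "kept_as_is",
    })
    return HarmonizedSet(exposure_id=exposure.trait_id,
                         outcome_id=outcome.trait_id, pairs=pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
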