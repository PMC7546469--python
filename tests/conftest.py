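import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsscreen.cassette import (
    STANDARD_CONCENTRATIONS_M,
    STANDARD_TEMPERATURES_C,
)
from hsscreen.survival import STANDARD_CELLS, SurvivalSurface, derivative_set

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CONCS = STANDARD_CONCENTRATIONS_M
TEMPS = STANDARD_TEMPERATURES_C


def make_surface(compound_id, values):
    """Build a SurvivalSurface from six values in STANDARD_CELLS order
    (or from an explicit cell -> Sn mapping)."""
    if isinstance(values, dict):
        sn = dict(values)
    else:
        sn = dict(zip(STANDARD_CELLS, values))
    return SurvivalSurface(compound_id, sn=sn)


def make_pair(compound_id, values):
    """Surface plus its derivative set."""
    surface = make_surface(compound_id, values)
    return surface, derivative_set(surface)


@pytest.fixture
def reference_pool():
    """Synthetic reference pool of 7 complete surfaces with distinct values
    in every cell (and hence distinct derivatives)."""
    rng = np.random.default_rng(20260930)
    pool = []
    for i in range(7):
        values = 0.5 + rng.permutation(12)[:6] * 0.07 + i * 0.013
        pool.append(make_pair(f"ref{i}", values))
    return pool


@pytest.fixture
def plate_rows():
    """Nine raw-count rows: one compound, 3 concentrations x 3 replicates
    at 38 C, plus its control wells."""
    rows = [["compound_id", "status", "conc_uM", "temp_C", "replicate", "alive", "total"]]
    for conc in (1, 10, 100):
        for rep in (1, 2, 3):
            rows.append(["cmpdA", "L", conc, 38, rep, 10 + rep, 20])
    return rows
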