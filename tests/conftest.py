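import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bilimr.instruments import HarmonizedInstrument, InstrumentSet

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_instrument_set(bx, by, sy, sx=None, eaf=None, exposure_n=100_000):
    """Build a small harmonized instrument set from plain arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, float)
    instruments = [
        HarmonizedInstrument(
            snp_id=f"s{j}", bx=float(bx[j]), sx=float(sx[j]),
            by=float(by[j]), sy=float(sy[j]), eaf=float(eaf[j]),
            aligned_allele="A", other_allele="G",
        )
        for j in range(len(bx))
    ]
    return InstrumentSet(instruments, exposure_n)


@pytest.fixture
def toy_instrument_set():
    rng = np.random.default_rng(42)
    k = 8
    bx = rng.uniform(0.05, 0.4, k)
    sy = rng.uniform(0.005, 0.02, k)
    by = 0.12 * bx + rng.normal(0, sy)
    sx = rng.uniform(0.002, 0.01, k)
    return make_instrument_set(bx, by, sy, sx=sx)


def pairs_from_diffs(diffs, column="z"):
    """Minimal 1:1 cohort frame whose case-minus-control differences in
    ``column`` equal ``diffs`` (control value 0)."""
    import pandas as pd

    rows = []
    for i, d in enumerate(diffs):
        rows.append({"pair_id": i, "is_case": True, "sex": "men",
                     "exposure": 1.0, column: float(d)})
        rows.append({"pair_id": i, "is_case": False, "sex": "men",
                     "exposure": 1.0, column: 0.0})
    return pd.DataFrame(rows)
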