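import numpy as np
import pandas as pd
import pytest

from tsmr import HarmonizedSet, load_instruments


@pytest.fixture(scope="session")
def severity():
    return load_instruments("severity")


@pytest.fixture(scope="session")
def hospitalization():
    return load_instruments("hospitalization")


@pytest.fixture(scope="session")
def susceptibility():
    return load_instruments("susceptibility")


@pytest.fixture(scope="session")
def all_sets(severity, hospitalization, susceptibility):
    return {
        "severity": severity,
        "hospitalization": hospitalization,
        "susceptibility": susceptibility,
    }


def make_set(bx, sx, by, sy, ids=None) -> HarmonizedSet:
    """Assemble a HarmonizedSet directly from arrays (test helper)."""
    n = len(bx)
    return HarmonizedSet(
        "exposure",
        "outcome",
        pd.DataFrame(
            {
                "snp": ids if ids is not None else [f"rs{i}" for i in range(n)],
                "beta_exposure": bx,
                "se_exposure": sx,
                "beta_outcome": by,
                "se_outcome": sy,
            }
        ),
    )


def random_set(rng, n=8) -> HarmonizedSet:
    """A generic random instrument set for oracle/property tests."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.005, 0.02, n)
    by = rng.normal(0.1 * bx, 0.01)
    sy = rng.uniform(0.005, 0.02, n)
    return make_set(bx, sx, by, sy)
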