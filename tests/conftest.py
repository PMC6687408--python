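import numpy as np
import pandas as pd
import pytest

import dtmr


@pytest.fixture(scope="session")
def demo_bundle():
    """Full-size demo scenario: 20k individuals, 3 drug classes planted."""
    return dtmr.build_scenario(dtmr.demo_config(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap scenario for structural tests."""
    cfg = dtmr.ccb_like_config(
        n_individuals=1500,
        n_phecodes=8,
        n_background_loci=5,
        seed=11,
        outcome_effects=(("CHD", 0.02, 0.1),),
    )
    return dtmr.build_scenario(cfg)


def random_ld(rng: np.random.Generator, n: int) -> dtmr.LdMatrix:
    """A random valid signed correlation matrix over n variants."""
    a = rng.standard_normal((n, n + 3))
    cov = a @ a.T
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return dtmr.LdMatrix([f"rs{i}" for i in range(n)], (r + r.T) / 2)


def random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random summary-stat records matching random_ld's variant ids."""
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": "1",
            "POS": np.arange(1, n + 1) * 1000,
            "EA": "A",
            "OA": "G",
            "EAF": rng.uniform(0.05, 0.95, n),
            "BETA": rng.normal(0, 0.5, n),
            "SE": rng.uniform(0.01, 0.2, n),
            "P": rng.uniform(0, 1, n),
            "N": 10_000,
        }
    )
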