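import numpy as np
import pandas as pd
import pytest

from plasmapanel.quantio import QuantMatrix
from plasmapanel.simulate import FixtureConfig, generate_fixture


def make_matrix(values: np.ndarray, conditions, arm="none", proteins=None,
                scale="raw") -> QuantMatrix:
    """Build a QuantMatrix from an array (proteins x runs) and condition labels."""
    values = np.asarray(values, dtype=float)
    n_prot, n_runs = values.shape
    proteins = proteins or [f"P{i}" for i in range(n_prot)]
    counts: dict = {}
    run_ids, reps = [], []
    for c in conditions:
        counts[c] = counts.get(c, 0) + 1
        run_ids.append(f"{arm}_{c}_r{counts[c]}")
        reps.append(counts[c])
    meta = pd.DataFrame({"condition": list(conditions), "arm": arm, "replicate": reps},
                        index=run_ids)
    return QuantMatrix(pd.DataFrame(values, index=proteins, columns=run_ids),
                       meta, scale=scale)


def triplicate_conditions():
    return [c for c in ("healthy", "I", "II", "III", "IV") for _ in range(3)]


@pytest.fixture(scope="session")
def single_arm_fixture():
    """Default-parameter fixture restricted to the non-depleted arm."""
    cfg = FixtureConfig(seed=42, arms=("none",), arm_retention=(1.0,))
    matrices, truth = generate_fixture(cfg)
    return matrices["none"], truth


@pytest.fixture(scope="session")
def full_fixture():
    """Default (four-arm) fixture."""
    cfg = FixtureConfig(seed=42)
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def driver_fixture():
    """Small, strongly separated fixture for fast classifier/panel tests:
    few proteins, large planted fold changes."""
    cfg = FixtureConfig(seed=7, n_proteins=40, n_de=10, de_fc_low=3.0,
                        de_fc_high=8.0, driver_panel_size=5,
                        arms=("none",), arm_retention=(1.0,))
    matrices, truth = generate_fixture(cfg)
    return matrices["none"], truth
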