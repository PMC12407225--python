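import numpy as np
import pandas as pd
import pytest

from panelbn.bn import TierConstraint
from panelbn.configs import compact_config, default_config, moderated_config
from panelbn.dataset import PanelDataset, VariableSpec
from panelbn.synthetic import build_ground_truth, generate_dataset, mcar, simulate_panel


@pytest.fixture(scope="session")
def compact_truth():
    return build_ground_truth(compact_config(2000, 7))


@pytest.fixture(scope="session")
def compact_dataset(compact_truth):
    """Complete 20-variable panel, n=2000, from the compact ground truth."""
    return simulate_panel(compact_truth, 2000, 7)


@pytest.fixture(scope="session")
def compact_missing(compact_dataset):
    """Same panel with 20% MCAR on all wave-stamped variables."""
    wave_cols = [c for c in compact_dataset.variables if "@" in c]
    return mcar(compact_dataset, 0.2, 3, columns=wave_cols)


@pytest.fixture(scope="session")
def compact_constraint(compact_dataset):
    return TierConstraint.from_specs(compact_dataset.specs)


@pytest.fixture(scope="session")
def moderated_dataset():
    """Two-wave moderated panel (~2500 participants per impairment level)."""
    return generate_dataset(moderated_config())


@pytest.fixture(scope="session")
def full_emulation_dataset():
    """The full pooled-panel emulation (52 variables, by-study missingness)."""
    return generate_dataset(default_config())


def random_clg_frame(seed: int, d: int, n: int = 300):
    """Random all-continuous dataset from a random DAG; used as a generic
    search/scoring instance.  Returns (frame, specs, true arcs)."""
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(d)]
    specs = {m: VariableSpec(m, "continuous", "determinant", "T1") for m in names}
    order = rng.permutation(d)
    truth = []
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < 0.5:
                truth.append(
                    (
                        names[order[i]],
                        names[order[j]],
                        rng.uniform(0.3, 1.0) * rng.choice([-1, 1]),
                    )
                )
    cols: dict[str, np.ndarray] = {}
    for i in range(d):
        v = names[order[i]]
        mu = np.zeros(n)
        for u, w, c in truth:
            if w == v:
                mu = mu + c * cols[u]
        cols[v] = mu + rng.normal(size=n)
    frame = pd.DataFrame(cols)[names]
    return frame, specs, {(u, v) for u, v, _ in truth}
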