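import numpy as np
import pandas as pd
import pytest

from temponet import InferenceConfig, WindowWeighting


@pytest.fixture
def expression_frame():
    """3 transcripts x 12 samples (4 time points x 3 replicates), log2 scale."""
    rng = np.random.default_rng(7)
    times = [1, 2, 4, 8]
    cols = [f"{t}h_rep{r}" for t in times for r in (1, 2, 3)]
    base = np.array(
        [
            [8.0, 8.6, 9.2, 9.0],  # up-regulated
            [9.0, 8.4, 8.0, 7.8],  # down-regulated
            [8.0, 8.05, 8.1, 8.02],  # flat (should be filtered)
        ]
    )
    vals = np.repeat(base, 3, axis=1) + rng.normal(0, 0.02, (3, 12))
    return pd.DataFrame(vals, index=["tx_up", "tx_down", "tx_flat"], columns=cols)


@pytest.fixture
def expression_file(tmp_path, expression_frame):
    path = tmp_path / "expr.tsv"
    expression_frame.to_csv(path, sep="\t")
    return path


@pytest.fixture
def tight_config():
    """Solver settings tight enough for oracle-level comparisons."""
    return InferenceConfig(
        tol_outer=1e-12, tol_inner=1e-13, max_cycles=5000
    )


@pytest.fixture
def no_window_config():
    """Delta=0: each transition regressed only on its own frame pair."""
    return InferenceConfig(window=WindowWeighting(delta=0))


def random_instance(rng, n_templates=3, n_times=4, n_samples=4):
    return [rng.standard_normal((n_templates, n_times)) for _ in range(n_samples)]
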