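import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from doaindex import synthetic_data as G


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """A small artifact-free synthetic session (5 min) used across modules."""
    traj = G.TrajectorySpec(
        duration_s=300.0, induction_s=30.0, maintenance_s=90.0, emergence_s=240.0
    )
    spec = G.GeneratorSpec(trajectory=traj, artifact_rate=0.0, noise_seed=42)
    return G.generate_session(spec)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run (12 sessions, seed 1), shared by the
    end-to-end checks."""
    from doaindex.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_default")
    results = run_pipeline(RunConfig(seed=1), out)
    return results, out
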