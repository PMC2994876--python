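import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from srnakit.config import PipelineConfig
from srnakit.pipeline import Pipeline
from srnakit.simulate import SimulationConfig, TruthTable, generate_reference


@pytest.fixture(scope="session")
def deep_run(tmp_path_factory):
    """Full pipeline on deep synthetic libraries (1e5 reads each).

    Shared by the parameter-recovery, novel-discovery and length-distribution
    checks so the expensive simulation and mapping run once per session.
    """
    work = tmp_path_factory.mktemp("deep_run")
    sim = SimulationConfig(seed=11, n_reads=100_000)
    pipe = Pipeline(PipelineConfig(seed=11, n_reads=100_000), work)
    outputs = pipe.run_all(sim)
    truth = TruthTable.read(work)
    return {
        "work": work,
        "outputs": outputs,
        "truth": truth,
        "sim_config": sim,
        "pipeline": pipe,
    }


@pytest.fixture(scope="session")
def small_bundle():
    """Reference bundle only (no reads), cheap enough for unit tests."""
    return generate_reference(SimulationConfig(seed=3, n_reads=1000))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Compact end-to-end run (1.5e4 reads) for pipeline-level unit tests."""
    work = tmp_path_factory.mktemp("small_run")
    sim = SimulationConfig(seed=5, n_reads=15_000)
    pipe = Pipeline(PipelineConfig(seed=5, n_reads=15_000), work)
    outputs = pipe.run_all(sim)
    return {"work": work, "outputs": outputs, "truth": TruthTable.read(work)}
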