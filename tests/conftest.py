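import pytest
from hypothesis import HealthCheck, settings

from draftaudit.pipeline import PipelineConfig, run_pipeline
from draftaudit.simulate import (
    DEFECT_CLASSES,
    DefectSpec,
    SimulationConfig,
    generate_truth,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL = SimulationConfig(n_chromosomes=2, n_genes=12, seed=7)


@pytest.fixture(scope="session")
def small_truth():
    """A small clean genome: 12 genes on 2 chromosomes."""
    return generate_truth(SMALL)


@pytest.fixture(scope="session")
def clean_run():
    """Identity-draft pipeline run (no defects) on the small genome."""
    return run_pipeline(PipelineConfig(sim=SMALL))


@pytest.fixture(scope="session")
def defected_run():
    """One defect of every class on a 20-gene genome."""
    cfg = PipelineConfig(
        sim=SimulationConfig(n_chromosomes=2, n_genes=20, seed=42),
        defects=tuple(DefectSpec(c, count=1) for c in DEFECT_CLASSES),
    )
    return run_pipeline(cfg)
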