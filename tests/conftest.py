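import numpy as np
import pytest

from gendulf import CohortSpec, ExpressionMatrix, simulate_case_control, simulate_healthy


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 10 samples with simple deterministic values."""
    rng = np.random.default_rng(42)
    values = np.abs(rng.normal(5, 2, size=(4, 10)))
    return ExpressionMatrix([f"G{i}" for i in range(4)], [f"S{i}" for i in range(10)], values)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Desk-scale cohort small enough for fast unit tests."""
    return CohortSpec(
        n_samples=150,
        n_genes=120,
        n_planted_pm=12,
        n_decoy_coregulated=6,
        n_true_dpm=6,
        n_step3_modifiers=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    healthy, truth = simulate_healthy(small_spec)
    study = simulate_case_control(small_spec, truth)
    return healthy, truth, study


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 400 samples x 1000 genes, 7+7 arms."""
    spec = CohortSpec(seed=3)
    healthy, truth = simulate_healthy(spec)
    study = simulate_case_control(spec, truth)
    return spec, healthy, truth, study
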