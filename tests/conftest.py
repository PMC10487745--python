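import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FULL_STUDY_SEED = 7


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The reference synthetic study at default scale: 50 families, 100
    planted variants per inheritance pattern, 5 candidates per pipeline
    class, plus background, at a fixed seed."""
    from famsv.simulate import SimConfig, simulate_cohort

    outdir = tmp_path_factory.mktemp("full_study")
    return simulate_cohort(SimConfig(), outdir, seed=FULL_STUDY_SEED)


@pytest.fixture(scope="session")
def full_result(full_study):
    from famsv.pipeline import run_study

    return run_study(full_study.outdir)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    from famsv.simulate import CANDIDATE_CLASSES, PATTERNS, SimConfig, simulate_cohort

    cfg = SimConfig(
        n_families=10,
        variants_per_pattern={p: 5 for p in PATTERNS},
        candidates_per_class={c: 2 for c in CANDIDATE_CLASSES},
    )
    outdir = tmp_path_factory.mktemp("small_study")
    return simulate_cohort(cfg, outdir, seed=11)
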