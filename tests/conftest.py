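import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_STUDY_SEED = 11


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small simulated multi-dataset study plus its pipeline result."""
    from riboassoc.pipeline import RunConfig, run_pipeline
    from riboassoc.simulate import SimulationConfig, simulate_study

    outdir = tmp_path_factory.mktemp("study")
    config = SimulationConfig(
        n_mrna=40,
        n_lnc_associated_translated=20,
        n_lnc_associated_untranslated=20,
        n_lnc_free=20,
        n_datasets=3,
    )
    manifest = simulate_study(config, outdir, seed=SMALL_STUDY_SEED)
    result = run_pipeline(RunConfig.from_yaml(outdir / "run.yaml"))
    return {"config": config, "manifest": manifest, "result": result, "dir": outdir}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
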