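import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from perturbatlas.simulate import default_fixture, simulate_dataset

SEED = 1


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(default_fixture("tiny", seed=SEED))


def _tiny_run_config(outdir):
    from perturbatlas.pipeline import RunConfig

    return RunConfig(
        outdir=str(outdir), seed=SEED, scale="tiny",
        qc={"min_genes": 50, "ambient_threshold": 0.09},
        de={"groupby": "neighborhood"},
        similarity={"groupby": "neighborhood", "n_pcs": 20, "n_hvg": 100,
                    "n_permutations": 50},
    )


@pytest.fixture(scope="session")
def tiny_pipeline_run(tmp_path_factory):
    """One full tiny-scale pipeline run (manifest, outdir)."""
    from perturbatlas.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("run_a")
    manifest = run_pipeline(_tiny_run_config(outdir))
    return manifest, outdir


@pytest.fixture(scope="session")
def tiny_pipeline_rerun(tmp_path_factory):
    """An independent second run with the identical config and seed."""
    from perturbatlas.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("run_b")
    manifest = run_pipeline(_tiny_run_config(outdir))
    return manifest, outdir


@pytest.fixture(scope="session")
def null_metrics():
    """Desk-scale no-effect study: every discovery is a false positive."""
    from perturbatlas.benchmarks import run_null_calibration

    return run_null_calibration(seed=SEED)


@pytest.fixture(scope="session")
def recovery_metrics():
    """Injected-effect study: depletion, DEG programmes, planted modules."""
    from perturbatlas.benchmarks import run_parameter_recovery

    return run_parameter_recovery(seed=SEED)
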