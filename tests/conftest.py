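import pytest

from paleofv.pipeline import run_all
from paleofv.scenarios import two_event_scenario
from paleofv.simulate import generate_scenario


@pytest.fixture(scope="session")
def two_event_dataset(tmp_path_factory):
    """The reference two-event scenario, generated once per session."""
    outdir = tmp_path_factory.mktemp("dataset")
    return generate_scenario(two_event_scenario(), outdir)


@pytest.fixture(scope="session")
def pipeline_run(two_event_dataset, tmp_path_factory):
    """Full pipeline results on the reference scenario."""
    outdir = tmp_path_factory.mktemp("run")
    report = run_all(two_event_dataset.root, outdir)
    return outdir, report
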