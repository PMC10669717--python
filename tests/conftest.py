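import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from drugcascade.fixtures import write_fixture_bundle
from drugcascade.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The study-shaped synthetic input bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(outdir, seed=0)


@pytest.fixture(scope="session")
def bundle_config(fixture_bundle):
    return PipelineConfig(
        corpus=str(fixture_bundle["corpus"]),
        lexicon=str(fixture_bundle["lexicon"]),
        catalogue=str(fixture_bundle["catalogue"]),
        drug_targets=str(fixture_bundle["drug_targets"]),
        gmt=str(fixture_bundle["gmt"]),
        ct=str(fixture_bundle["ct"]),
        elisa=str(fixture_bundle["elisa"]),
        seed=0,
    )


@pytest.fixture(scope="session")
def bundle_report(bundle_config, tmp_path_factory):
    """One full pipeline run on the bundle, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    report = run_pipeline(bundle_config, outdir)
    return report, outdir
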