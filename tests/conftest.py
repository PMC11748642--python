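import pytest

from isletpep import FixtureConfig, make_fixture, pipeline


@pytest.fixture(scope="session")
def fixture_bundle():
    """One shared synthetic study (seed 1) with spectra."""
    return make_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(fixture_bundle):
    """Full pipeline result on the shared study."""
    db = pipeline.build_database(fixture_bundle)
    result = pipeline.run_pipeline(
        fixture_bundle.psms, db, fixture_bundle.annotations,
        fixture_bundle.ranks, ptm_spectra=fixture_bundle.ptm_spectra,
    )
    return fixture_bundle, result
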