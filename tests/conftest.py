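import pytest

from phytoquant import io as pio


@pytest.fixture(scope="session")
def printed_effects():
    """Published screening effects (14 contrasts x TF/CA/FL)."""
    return pio.load_screening_effects()


@pytest.fixture(scope="session")
def surface_models():
    """Published quadratic surface models keyed by response."""
    return pio.load_surface_models()


@pytest.fixture(scope="session")
def composition():
    """Packaged per-compound composition table and analyte specs."""
    from phytoquant.quantification import fixture_samples

    samples, specs = fixture_samples()
    return {s.sample_id: s for s in samples}, specs
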