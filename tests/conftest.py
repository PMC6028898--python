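"""Shared fixtures: one small but complete synthetic study per session."""

import pytest

from phenoml import FeatureBuilder, simulate


@pytest.fixture(scope="session")
def tiny():
    """A compact study: 12 stations, 3 years, default truth parameters."""
    return simulate(n_stations=12, years=range(2007, 2010), seed=5)


@pytest.fixture(scope="session")
def tiny_builder(tiny):
    return FeatureBuilder.from_dataset(tiny)
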