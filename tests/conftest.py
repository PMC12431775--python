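"""Shared fixtures: synthetic bundles are generated once per session."""

import pytest

from crelink.pipeline import link_all
from crelink.synthetic_data import SynthConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle_default():
    """Default study conditions (evidence noise on)."""
    return simulate_bundle(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def bundle_noiseless():
    """Zero evidence noise: exact-recovery conditions."""
    return simulate_bundle(SynthConfig.noiseless(seed=0))


@pytest.fixture(scope="session")
def bundle_mini():
    return simulate_bundle(SynthConfig.mini(seed=5))


@pytest.fixture(scope="session")
def linked_noiseless(bundle_noiseless):
    """(gene -> LinkRecords, gene -> TAD) for the noiseless bundle."""
    return link_all(bundle_noiseless, seed=11)


@pytest.fixture(scope="session")
def linked_default(bundle_default):
    return link_all(bundle_default, seed=11)
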