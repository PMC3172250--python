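import warnings

import pytest

from mirtime.synthetic import SynthConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Module warnings (empty files, constant rows) are asserted explicitly
    where they matter; keep the rest out of the test log."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_cfg() -> SynthConfig:
    """A fast, fully planted configuration for structural tests."""
    return SynthConfig(
        seed=1,
        n_mirna=60,
        n_mrna=200,
        n_planted_up=12,
        n_planted_updown=8,
        library_size=200_000,
        targets_per_mirna=3,
        n_terms=20,
        n_planted_terms=2,
    )
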