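import warnings

import pytest

from panprop import synthetic as syn


@pytest.fixture
def small_pangenome():
    """A small high-quality pangenome with planted markers (fixed seed)."""
    cfg = syn.PangenomeConfig(
        n_focal=24, n_background=16, n_core_focal=30, n_markers=5,
        n_shared=50, n_accessory=50, completeness_range=(0.95, 1.0),
        contamination_rate=0.01, seed=11,
    )
    return syn.simulate_pangenome(cfg)


@pytest.fixture
def quiet():
    """Suppress the package's own data-quality warnings in bulk loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
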