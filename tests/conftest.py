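import numpy as np
import pytest

from henspec import dataset, fcwt, synth


@pytest.fixture(scope="session")
def small_flock():
    """40 labeled comb spectra (7:3) on the full 300-band grid."""
    cfg = synth.SynthConfig(n_hens=40, seed=11)
    return synth.make_flock_spectra(cfg)


@pytest.fixture(scope="session")
def small_feature_dataset(small_flock):
    """Feature maps of the small flock at a reduced scale count (24 x 300)."""
    scales = fcwt.make_scales(5, 6, 24)
    ds = dataset.spectra_to_features(small_flock, scales)
    return dataset.normalize_features(ds, method="global")
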