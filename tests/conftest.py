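import numpy as np
import pytest

import fallseg as fs


@pytest.fixture(scope="session")
def small_dataset():
    """A 30 fall / 30 ADL dataset at 50 Hz, default (hardest) difficulty."""
    cfg = fs.GeneratorConfig(
        sampling_rate_hz=50.0, n_fall_records=30, n_adl_records=30, seed=3
    )
    records, manifest = fs.generate_dataset(cfg)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def prepared(small_dataset):
    """Event-centered records of the small dataset at the 1.4 g threshold."""
    _, records, _ = small_dataset
    return fs.prepare_event_centered(records)
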