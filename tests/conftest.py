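import numpy as np
import pytest

from imbalsim2real import DomainSample, assemble_dataset


@pytest.fixture
def toy_dataset():
    """4 sim + 3 real samples, 2 pairs, 2-dim covariates."""
    source = [
        DomainSample((0.0, 1.0), 0.5, "sim"),
        DomainSample((0.5, 2.0), 1.0, "sim"),
        DomainSample((1.0, 3.0), 1.5, "sim"),
        DomainSample((-1.0, 4.0), -2.0, "sim"),
    ]
    target = [
        DomainSample((0.0, 1.0), 2.5, "real"),
        DomainSample((0.5, 2.0), 3.0, "real"),
        DomainSample((-0.5, 0.5), 1.0, "real"),
    ]
    return assemble_dataset(source, target, [(0, 0), (1, 1)])
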