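import numpy as np
import pytest

from myxoedit import synthetic


@pytest.fixture(scope="session")
def small_transcriptome():
    """Six synthetic gene pairs spanning the conservation range."""
    cfg = synthetic.SimulationConfig(n_genes=6, protein_len_range=(100, 160))
    return synthetic.simulate_transcriptome(cfg, 20240)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genomic(rng, n, gc=0.25):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
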