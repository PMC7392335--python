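import numpy as np
import pytest

from dualgenome import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_grammar():
    return synthetic.default_grammar(
        n_motifs=6, tissues=("alpha", "beta"), seed=7, distal_decay=2000.0,
        substitution_rate=0.02,
    )


@pytest.fixture(scope="session")
def tiny_pair(tmp_path_factory, tiny_grammar):
    """Small two-species benchmark shared by read-only tests."""
    out = tmp_path_factory.mktemp("tiny_pair")
    pair = synthetic.generate_species_pair(
        tiny_grammar, n_chrom=2, chrom_len=65_536, shared_fraction=0.5,
        out_dir=str(out), block_size=8192,
    )
    synthetic.simulate_signal_tracks(pair, tiny_grammar)
    return pair
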