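import numpy as np
import pytest

from songmem import chunking, working_memory
from songmem.spectral_timing import ConditioningProtocol, TimingSpectrum, train
from songmem.working_memory import ItemSequence, WMParams, present_sequence


@pytest.fixture
def wm_params():
    """Frozen bottom-up-only storage parameters."""
    return WMParams()


@pytest.fixture
def wm_params_topdown():
    """Frozen storage parameters with top-down expectation support."""
    return WMParams(top_down_gain=working_memory.DEFAULT_TOP_DOWN)


@pytest.fixture
def store(wm_params_topdown):
    """Store a token sequence with top-down support (spans up to 7)."""
    def _store(tokens):
        return present_sequence(ItemSequence(list(tokens)), wm_params_topdown)
    return _store


@pytest.fixture
def word_network(store):
    """Chunk network trained on MY, SELF, ELF then MYSELF (in that order)."""
    net = chunking.ChunkNetwork()
    ids = {}
    for word in ("MY", "SELF", "ELF", "MYSELF"):
        ids[word] = chunking.learn(store(word), net, label=word)
    return net, ids


def trained_spectrum(isi: float, n_trials: int = 5) -> TimingSpectrum:
    sp = TimingSpectrum()
    train(sp, ConditioningProtocol(ISI=isi, n_trials=n_trials))
    return sp


@pytest.fixture(scope="session")
def spectrum_400ms():
    return trained_spectrum(0.4)
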