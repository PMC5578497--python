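import numpy as np
import pytest

from widelex.stimuli import FeatureConfig, Lexicon, bundled_lexicon, cue_cache


@pytest.fixture(scope="session")
def lex():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def cues():
    """Session-wide memoized cue mapper under the default feature config."""
    return cue_cache(FeatureConfig())


@pytest.fixture()
def small_lex():
    return Lexicon(["TORE", "WEND", "BOOR", "TARE", "KRIS"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
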