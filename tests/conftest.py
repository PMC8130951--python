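import pytest
from hypothesis import HealthCheck, settings

from recallkit import Lexicon, WordList

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def butterfly_lexicon() -> Lexicon:
    """Morpheme lexicon covering the classic compound-name examples."""
    return Lexicon.from_tokens(
        [
            "metal", "mark", "mask", "angle", "angel", "wing", "spot",
            "copper", "silver", "tail", "sail", "pearl", "streak",
        ]
    )


@pytest.fixture(scope="session")
def small_wordlist() -> WordList:
    return WordList.from_tokens(
        ["metalmark", "anglewing", "coppertail", "silverspot", "pearlstreak"]
    )
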