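import pytest
from hypothesis import settings

from wordinfo import EmbedderSpec, Sentence

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TABLE1_TEXT = ("even though most of his inventions were not actually built in his "
               "lifetime, many of today’s modern machines can be traced back "
               "to some of his original designs")

# A fixture corpus of English sentences: varied length, punctuation, repeats;
# 200+ word tokens in total.
FIXTURE_TEXTS = [
    "the wedding was ruined by the heavy rain and snow",
    "the royal couple married in a beautiful wedding ceremony",
    "The athlete ran as she crossed the finish line of the marathon",
    "The bride ran as she saw the groom in the wedding",
    "a quiet library invites long afternoons of careful reading",
    "storms battered the coast for three days without pause",
    "children chased the bright kite across the open field",
    "her grandmother's recipe called for honey, figs, and patience",
    "the committee postponed its final decision until spring",
    "an old lighthouse guided the fishing boats home at night",
    "scientists measured tiny changes in the glacier's slow retreat",
    "the orchestra tuned quietly before the conductor arrived",
    "fresh bread cooled on the windowsill of the tiny bakery",
    "two rival chess players studied the board in silence",
    "the museum unveiled a restored painting from the last century",
    "volunteers planted oak saplings along the dusty road",
    "morning fog settled over the valley and hid the village",
    "the engineer traced the fault to a single corroded wire",
    "travelers swapped stories beside the station's flickering lamp",
    "a sudden applause filled the hall when the curtain fell",
    "the ferry crossed the grey strait twice every winter morning",
    "an impatient crowd gathered outside the bakery before dawn",
    "the observatory's dome opened slowly under a cold clear sky",
]


@pytest.fixture(scope="session")
def spec() -> EmbedderSpec:
    return EmbedderSpec(name="reference", dim=64, seed=7)


@pytest.fixture(scope="session")
def table1_sentence() -> Sentence:
    return Sentence.from_text(TABLE1_TEXT, id="table1", language="en")


@pytest.fixture(scope="session")
def fixture_corpus() -> list[Sentence]:
    return [Sentence.from_text(t, id=f"s{i}", language="en")
            for i, t in enumerate(FIXTURE_TEXTS)]
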