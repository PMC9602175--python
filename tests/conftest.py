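import datetime

import pytest

from psgminer import PSGNote, SynthesisConfig, generate_notes


@pytest.fixture
def note_factory():
    def make(body: str, title: str = "Polysomnography report", note_id: str = "n1") -> PSGNote:
        return PSGNote(
            note_id=note_id,
            patient_id="p1",
            visit_date=datetime.date(2015, 6, 1),
            title=title,
            body=body,
            cpt_codes=frozenset({"95810"}),
        )

    return make


@pytest.fixture(scope="session")
def default_corpus():
    """200 synthetic notes under the default study conditions, seed 7."""
    return generate_notes(SynthesisConfig(n_notes=200, seed=7))


@pytest.fixture(scope="session")
def canonical_corpus():
    """200 synthetic notes using only the canonical template."""
    return generate_notes(SynthesisConfig(n_notes=200, seed=7, template_mix={"canonical": 1.0}))
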