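import pytest

import rarescan as rs


@pytest.fixture(scope="session")
def normalizer():
    return rs.Normalizer()


@pytest.fixture(scope="session")
def entries():
    return rs.bundled_dictionary()


@pytest.fixture(scope="session")
def index(entries, normalizer):
    return rs.build_index(entries, normalizer)


@pytest.fixture(scope="session")
def triggers():
    return rs.bundled_triggers()


@pytest.fixture(scope="session")
def panel():
    return rs.bundled_panel()


def make_notes(texts):
    """Build one ClinicalNote per (id, text); patient == note for simplicity."""
    return [
        rs.ClinicalNote(patient_id=k, episode_id=k, note_id=k, date="2020-01-01", text=v)
        for k, v in texts.items()
    ]
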