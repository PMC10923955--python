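from __future__ import annotations

import pytest

from melboard import load_knowledge_base, replay_preset
from melboard.records import CaseRecord


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def preset_run():
    """Study-replica preset cohort and its full pipeline outcome."""
    return replay_preset(seed=7)


def make_case(**over) -> CaseRecord:
    """A complete, uncomplicated localized melanoma registration."""
    fields = dict(
        case_id="C1",
        age=60.0,
        ecog=0,
        breslow_mm=2.5,
        ulceration="absent",
        slnb="negative",
        presentation="primary_localized",
    )
    fields.update(over)
    return CaseRecord(**fields)
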