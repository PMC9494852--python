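import datetime

import pytest
from hypothesis import HealthCheck, settings

from migrascore import EncounterNote, Lexicon, Specialty

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon()


@pytest.fixture
def make_note():
    def _make(
        narrative: str,
        encounter_id: str = "e1",
        patient_id: str = "p1",
        chief_complaint: str = "",
        date: str = "2019-03-01",
        specialty: Specialty = Specialty.NEUROLOGY,
    ) -> EncounterNote:
        return EncounterNote(
            patient_id=patient_id,
            encounter_id=encounter_id,
            date=datetime.date.fromisoformat(date),
            specialty=specialty,
            chief_complaint=chief_complaint,
            narrative=narrative,
        )

    return _make
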