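import pytest

from icfmon.harmonize import ICFDatum, Snapshot
from icfmon.icf_model import Qualifier, parse_code
from icfmon.mapping import bundled_crosswalk
from icfmon.monitor import PersonProfile


@pytest.fixture(scope="session")
def crosswalk():
    return bundled_crosswalk()


def make_snapshot(person_id="P1", year=2013, **code_values) -> Snapshot:
    """Snapshot with measured data, e.g. make_snapshot(d550=2, d540=1)."""
    snap = Snapshot(person_id=person_id, year=year)
    for code, value in code_values.items():
        snap.put(ICFDatum(parse_code(code), Qualifier(value), "measured", ("test",)))
    return snap


def make_profile(person_id="P1", snapshots=None, **demo) -> PersonProfile:
    defaults = dict(age=40.0, gender="male", years_from_diagnosis=10.0,
                    disease="traumatic brain injury", origin="traumatic")
    defaults.update(demo)
    if snapshots is None:
        snapshots = {2013: make_snapshot(person_id, 2013, d550=2)}
    return PersonProfile(person_id=person_id, snapshots=snapshots, **defaults)


@pytest.fixture(scope="session")
def emotional_cohort():
    """One Table-1-like synthetic cohort shared by the slower tests."""
    from icfmon.synthetic import emotional_preset, generate

    return generate(emotional_preset(n=419, seed=11))
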