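import json
import random

import pytest

from msud_buddy import (
    FormulaSelection,
    PatientProfile,
    PlasmaPanel,
    load_kb,
    load_tree,
)


@pytest.fixture(scope="session")
def kb():
    return load_kb()


@pytest.fixture()
def default_tree():
    """Fresh copy of the packaged rule tree (trees are mutable)."""
    from importlib import resources

    raw = (resources.files("msud_buddy") / "data" / "default_tree.json").read_text()
    return load_tree(json.loads(raw))


@pytest.fixture()
def worked_example(kb):
    """The reference patient: 3 months, 5 kg, in-range plasma panel,
    Similac + Ketonex-1."""
    return (
        PatientProfile(age_months=3, weight_kg=5.0),
        PlasmaPanel(leucine=80, isoleucine=17, valine=55),
        FormulaSelection(commercial_name="Similac", medical_name="Ketonex-1"),
    )


def random_patient(rng: random.Random):
    """A random in-scope patient for the safety sweeps: age 0-6 months,
    weight 2-10 kg, plasma values spanning in- and out-of-band levels."""
    return (
        PatientProfile(
            age_months=rng.uniform(0, 6),
            weight_kg=rng.uniform(2, 10),
        ),
        PlasmaPanel(
            leucine=rng.uniform(0, 600),
            isoleucine=rng.uniform(0, 600),
            valine=rng.uniform(0, 600),
        ),
    )
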