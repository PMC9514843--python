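import pandas as pd
import pytest

from csrkit import ContaminantRates, GeneratorConfig
from csrkit.synthetic import ROSTER_COLUMNS


def make_person(household_id, person_id, role, sex, age, ethnicity="Indian",
                birth_country=None, adopted=False, year=2016, country="Canada"):
    if birth_country is None:
        birth_country = country if role == "child" else "India"
    return dict(
        household_id=household_id, person_id=person_id, role=role, sex=sex,
        age_years=age, ethnicity=ethnicity, birth_country=birth_country,
        adopted_flag=adopted, census_year=year, country_of_residence=country,
    )


@pytest.fixture
def clean_config():
    """Contaminant-free generator config with selection at second births
    following a first daughter."""
    return GeneratorConfig(
        n_families=5000,
        seed=11,
        contaminant_rates=ContaminantRates(),
        selection_prob={"2,0,1": 0.5},
    )


@pytest.fixture
def twelve_household_roster():
    """Hand-built roster covering every exclusion type, with the statuses a
    correct filter pass must produce."""
    rows = []

    def hh(hid, people):
        rows.extend(people)

    # eligible two-child family
    hh("h01", [make_person("h01", "h01_m", "mother", "female", 34),
               make_person("h01", "h01_f", "father", "male", 36),
               make_person("h01", "h01_c1", "child", "female", 6),
               make_person("h01", "h01_c2", "child", "male", 3)])
    # single father
    hh("h02", [make_person("h02", "h02_f", "father", "male", 40),
               make_person("h02", "h02_c1", "child", "female", 8),
               make_person("h02", "h02_c2", "child", "male", 5)])
    # same-sex couple (two fathers)
    hh("h03", [make_person("h03", "h03_f1", "father", "male", 38),
               make_person("h03", "h03_f2", "father", "male", 37),
               make_person("h03", "h03_c1", "child", "male", 4)])
    # adopted child
    hh("h04", [make_person("h04", "h04_m", "mother", "female", 30),
               make_person("h04", "h04_f", "father", "male", 31),
               make_person("h04", "h04_c1", "child", "female", 2, adopted=True)])
    # twins (suspected multifetal)
    hh("h05", [make_person("h05", "h05_m", "mother", "female", 33),
               make_person("h05", "h05_f", "father", "male", 35),
               make_person("h05", "h05_c1", "child", "female", 7),
               make_person("h05", "h05_c2", "child", "male", 7)])
    # five children
    hh("h06", [make_person("h06", "h06_m", "mother", "female", 39),
               make_person("h06", "h06_f", "father", "male", 41)] +
       [make_person("h06", f"h06_c{i}", "child", "male" if i % 2 else "female",
                    12 - 2 * i) for i in range(1, 6)])
    # child older than 14
    hh("h07", [make_person("h07", "h07_m", "mother", "female", 42),
               make_person("h07", "h07_f", "father", "male", 44),
               make_person("h07", "h07_c1", "child", "male", 16),
               make_person("h07", "h07_c2", "child", "female", 10)])
    # eligible single newborn
    hh("h08", [make_person("h08", "h08_m", "mother", "female", 27),
               make_person("h08", "h08_f", "father", "male", 28),
               make_person("h08", "h08_c1", "child", "female", 0)])
    # eligible four-child family (at the size cap)
    hh("h09", [make_person("h09", "h09_m", "mother", "female", 38),
               make_person("h09", "h09_f", "father", "male", 40)] +
       [make_person("h09", f"h09_c{i}", "child", "female" if i < 3 else "male",
                    13 - 3 * i) for i in range(1, 5)])
    # childless household: dropped silently
    hh("h10", [make_person("h10", "h10_m", "mother", "female", 50),
               make_person("h10", "h10_f", "father", "male", 52)])
    # eligible domestic comparator family
    hh("h11", [make_person("h11", "h11_m", "mother", "female", 31,
                           ethnicity="Canadian", birth_country="Canada"),
               make_person("h11", "h11_f", "father", "male", 32,
                           ethnicity="Canadian", birth_country="Canada"),
               make_person("h11", "h11_c1", "child", "male", 5,
                           ethnicity="Canadian")])
    # eligible second-generation family
    hh("h12", [make_person("h12", "h12_m", "mother", "female", 29,
                           birth_country="Canada"),
               make_person("h12", "h12_f", "father", "male", 30,
                           birth_country="Canada"),
               make_person("h12", "h12_c1", "child", "female", 3),
               make_person("h12", "h12_c2", "child", "male", 1)])

    roster = pd.DataFrame(rows, columns=ROSTER_COLUMNS)
    expected = {
        "h01": ("eligible", ""),
        "h02": ("excluded", "single_father"),
        "h03": ("excluded", "same_sex_couple"),
        "h04": ("excluded", "adopted"),
        "h05": ("excluded", "multifetal"),
        "h06": ("excluded", "family_size"),
        "h07": ("excluded", "child_over_age"),
        "h08": ("eligible", ""),
        "h09": ("eligible", ""),
        "h11": ("eligible", ""),
        "h12": ("eligible", ""),
    }
    return roster, expected
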