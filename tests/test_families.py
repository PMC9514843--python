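"""Family reconstruction, birth ordering, eligibility filters, generation
classification, and the direct birth-history ingest path."""

import dataclasses

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csrkit import (
    ContaminantRates,
    EligibilityRules,
    Family,
    GeneratorConfig,
    apply_filters,
    assign_birth_orders,
    build_families,
    classify_generation,
    exclusion_audit,
    generate_population,
    ingest_birth_history,
    reconstruct_families,
    roster_frame,
)
from csrkit.families import BirthRecord

from conftest import make_person

RULES = EligibilityRules()


def frame(rows):
    return pd.DataFrame(rows)


class TestReconstruct:
    def test_canonical_household(self):
        roster = frame([
            make_person("h1", "m", "mother", "female", 32),
            make_person("h1", "f", "father", "male", 33),
            make_person("h1", "c1", "child", "female", 6),
            make_person("h1", "c2", "child", "male", 3),
        ])
        (fam,) = reconstruct_families(roster)
        assert [b.birth_order for b in fam.births] == [1, 2]
        assert [b.sex for b in fam.births] == ["female", "male"]
        assert fam.generation == "first" and fam.origin == "India"
        assert fam.status == "eligible"

    def test_fatherless_household_with_mother_is_kept(self):
        roster = frame([
            make_person("h1", "m", "mother", "female", 32),
            make_person("h1", "c1", "child", "male", 2),
        ])
        (fam,) = build_families(roster)
        assert fam.status == "eligible"

    def test_no_mother_household_excluded_as_single_father(self):
        roster = frame([
            make_person("h1", "f", "father", "male", 40),
            make_person("h1", "c1", "child", "female", 8),
            make_person("h1", "c2", "child", "male", 5),
        ])
        (fam,) = reconstruct_families(roster)
        assert fam.status == "excluded"
        assert fam.exclusion_reason == "single_father"

    def test_duplicate_person_id_rejected(self):
        roster = frame([
            make_person("h1", "x", "mother", "female", 30),
            make_person("h1", "x", "child", "male", 2),
        ])
        with pytest.raises(ValueError, match="duplicate person_id"):
            reconstruct_families(roster)

    def test_multi_mother_household_rejected(self):
        roster = frame([
            make_person("h1", "m1", "mother", "female", 30),
            make_person("h1", "m2", "mother", "female", 31),
            make_person("h1", "c1", "child", "male", 2),
        ])
        with pytest.raises(ValueError, match="mother rows"):
            reconstruct_families(roster)

    def test_childless_household_dropped(self):
        roster = frame([
            make_person("h1", "m", "mother", "female", 50),
            make_person("h1", "f", "father", "male", 52),
        ])
        assert reconstruct_families(roster) == []

    def test_ground_truth_recovered_on_synthetic_roster(self):
        cfg = GeneratorConfig(n_families=1000, seed=21)
        persons, truth = generate_population(cfg)
        families = {f.family_id: f for f in build_families(roster_frame(persons))}
        clean = truth[truth["contaminants"] == ""]
        for hid, fam_truth in clean.groupby("household_id"):
            fam = families[hid]
            got = [(b.birth_order, b.sex) for b in fam.births]
            want = list(
                fam_truth.sort_values("birth_order")[["birth_order", "sex"]]
                .itertuples(index=False, name=None)
            )
            assert got == want, hid


class TestBirthOrders:
    def test_descending_age_maps_to_ascending_order(self):
        children = [
            make_person("h", f"c{i}", "child", s, a)
            for i, (a, s) in enumerate([(9, "female"), (5, "female"), (2, "male")])
        ]
        births = assign_birth_orders(children)
        assert [b.birth_order for b in births] == [1, 2, 3]
        assert births[2].n_prior_daughters == 2
        assert births[2].n_prior_sons == 0

    def test_equal_ages_flagged_multifetal(self):
        children = [make_person("h", "c1", "child", "female", 7),
                    make_person("h", "c2", "child", "male", 7)]
        births = assign_birth_orders(children)
        assert all(b.multifetal_flag for b in births)

    def test_single_newborn(self):
        (b,) = assign_birth_orders([make_person("h", "c1", "child", "female", 0)])
        assert (b.birth_order, b.n_prior_sons, b.n_prior_daughters) == (1, 0, 0)


class TestFilters:
    def _family(self, births, n_mothers=1, n_fathers=1):
        return Family(
            family_id="x", mother_ethnicity="Indian", mother_birth_country="India",
            generation="first", origin="India", country_of_residence="Canada",
            census_year=2016, births=births, n_mothers=n_mothers, n_fathers=n_fathers,
        )

    def _births(self, sexes, ages=None, **flags):
        ages = ages or list(range(len(sexes) * 3, 0, -3))
        out, sons, daughters = [], 0, 0
        for i, (sex, age) in enumerate(zip(sexes, ages)):
            out.append(BirthRecord(i + 1, sex, sons, daughters, age, **flags))
            if sex == "female":
                daughters += 1
            else:
                sons += 1
        return out

    def test_five_children_excluded_for_size(self):
        fam = apply_filters(self._family(self._births(["female"] * 5)), RULES)
        assert (fam.status, fam.exclusion_reason) == ("excluded", "family_size")

    def test_adopted_child_excluded(self):
        fam = apply_filters(
            self._family(self._births(["male"], adopted_flag=True)), RULES)
        assert fam.exclusion_reason == "adopted"

    def test_clean_three_child_family_eligible(self):
        fam = apply_filters(
            self._family(self._births(["female", "male", "male"], [10, 7, 2])), RULES)
        assert fam.status == "eligible" and fam.exclusion_reason == ""

    def test_first_matching_reason_wins(self):
        # adopted precedes family_size in the fixed evaluation order
        fam = apply_filters(
            self._family(self._births(["male"] * 5, adopted_flag=True)), RULES)
        assert fam.exclusion_reason == "adopted"

    def test_filtering_never_mutates_births(self):
        births = self._births(["female"] * 5)
        fam = self._family(births)
        out = apply_filters(fam, RULES)
        assert out.births is births and fam.status == "eligible"

    def test_monotonic_adding_contaminant_never_restores_eligibility(self):
        base = self._family(self._births(["female", "male"], [6, 3]))
        assert apply_filters(base, RULES).status == "eligible"
        variants = [
            dataclasses.replace(base, n_mothers=0),  # single father
            dataclasses.replace(base, n_mothers=0, n_fathers=2),  # same-sex
            dataclasses.replace(base, births=self._births(["female", "male"],
                                                          [6, 3], adopted_flag=True)),
            dataclasses.replace(base, births=self._births(["female", "male"],
                                                          [6, 6], multifetal_flag=True)),
            dataclasses.replace(base, births=self._births(["female"] * 5)),
            dataclasses.replace(base, births=self._births(["female", "male"], [15, 3])),
        ]
        for fam in variants:
            assert apply_filters(fam, RULES).status == "excluded"

    def test_partition_and_single_reason(self, twelve_household_roster):
        roster, expected = twelve_household_roster
        families = build_families(roster)
        assert len(families) == len(expected)
        for fam in families:
            assert (fam.status, fam.exclusion_reason) == expected[fam.family_id]
        audit = exclusion_audit(families)
        assert audit["eligible"] + sum(
            v for k, v in audit.items() if k != "eligible") == len(families)


class TestGeneration:
    def test_first_generation(self):
        assert classify_generation("India", "Indian", "Canada", RULES) == ("first", "India")

    def test_second_generation(self):
        assert classify_generation("Canada", "Indian", "Canada", RULES) == ("second", "India")

    def test_domestic(self):
        assert classify_generation("Canada", "Canadian", "Canada", RULES) == (
            "domestic", "Canada")

    def test_origin_born_nonlocal_ethnicity_is_other(self):
        gen, origin = classify_generation("India", "Chinese", "Canada", RULES)
        assert gen == "other"

    def test_unmapped_ethnicity_other_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            gen, origin = classify_generation("Peru", "Peruvian", "Canada", RULES)
        assert (gen, origin) == ("other", None)
        assert "unmapped ethnicity" in caplog.text


class TestBirthHistoryIngest:
    def _rows(self, entries, mother="m1"):
        return pd.DataFrame(
            [dict(mother_id=m, country_of_residence="India", census_year=2015,
                  mother_ethnicity="Indian", mother_birth_country="India",
                  birth_order=o, sex=s)
             for m, o, s in entries]
        )

    def test_two_birth_family(self):
        (fam,) = ingest_birth_history(self._rows([("m1", 1, "female"),
                                                  ("m1", 2, "male")]))
        assert fam.births[1].n_prior_daughters == 1
        assert fam.status == "eligible"

    def test_gap_in_orders_rejected(self):
        with pytest.raises(ValueError, match="not contiguous"):
            ingest_birth_history(self._rows([("m1", 1, "female"), ("m1", 3, "male")]))

    def test_duplicate_order_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ingest_birth_history(self._rows([("m1", 1, "female"), ("m1", 1, "male")]))

    def test_size_filter_applies_without_ages(self):
        rows = self._rows([("m1", i, "female") for i in range(1, 6)])
        (fam,) = ingest_birth_history(rows)
        assert fam.exclusion_reason == "family_size"


@settings(derandomize=True, max_examples=200)
@given(
    sexes=st.lists(st.sampled_from(["female", "male"]), min_size=1, max_size=6),
    data=st.data(),
)
def test_priors_invariant_under_random_families(sexes, data):
    """For every emitted BirthRecord, prior counts sum to order-1 and match
    the sexes of lower-order siblings."""
    n = len(sexes)
    ages = data.draw(
        st.lists(st.integers(0, 20), min_size=n, max_size=n, unique=True)
    )
    children = [make_person("h", f"c{i}", "child", s, a)
                for i, (s, a) in enumerate(zip(sexes, ages))]
    births = assign_birth_orders(children)
    ordered_sexes = [b.sex for b in births]
    for i, b in enumerate(births):
        assert b.birth_order == i + 1
        assert b.n_prior_sons + b.n_prior_daughters == b.birth_order - 1
        assert b.n_prior_sons == ordered_sexes[:i].count("male")
        assert b.n_prior_daughters == ordered_sexes[:i].count("female")
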