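"""Family reconstruction and eligibility filtering.

Two input modes feed the pipeline:

* **Roster mode** (census extracts): households are grouped, children are
  attached to the household's mother, and birth order is reconstructed from
  age — the own-children method. Integer ages make twins (and siblings born
  under a year apart) indistinguishable; equal-aged siblings are flagged as
  suspected multifetal and the family is excluded.
* **Birth-history mode** (fertility surveys): birth orders are stated
  directly; prior-sex counts are recomputed and validated, and age-based
  rules are skipped because the format carries no ages.

Exclusion reasons are evaluated in a fixed order so audit counts are
reproducible: no_mother/single_father, same_sex_couple, adopted, multifetal,
family_size, child_over_age. A family gets exactly one reason — the first
that matches.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .synthetic import PersonRecord, roster_frame

__all__ = [
    "BirthRecord",
    "Family",
    "EligibilityRules",
    "reconstruct_families",
    "assign_birth_orders",
    "apply_filters",
    "classify_generation",
    "ingest_birth_history",
    "build_families",
    "families_to_frame",
    "exclusion_audit",
]

logger = logging.getLogger(__name__)

#: Fixed evaluation order of exclusion reasons.
EXCLUSION_ORDER = [
    "no_mother",
    "single_father",
    "same_sex_couple",
    "adopted",
    "multifetal",
    "family_size",
    "child_over_age",
]

DEFAULT_ORIGIN_MAP = {
    "Indian": "India",
    "Chinese": "China",
    "Bangladeshi": "Bangladesh",
    "Pakistani": "Pakistan",
    "Sri Lankan": "Sri Lanka",
    "Korean": "South Korea",
    "Hong Konger": "Hong Kong",
}

DEFAULT_DOMESTIC = {"Australian", "Canadian", "British", "American"}

FAMILY_FRAME_COLUMNS = [
    "family_id",
    "status",
    "exclusion_reason",
    "country_of_residence",
    "census_year",
    "mother_ethnicity",
    "mother_birth_country",
    "generation",
    "origin",
    "birth_order",
    "sex",
    "age_years",
    "n_prior_sons",
    "n_prior_daughters",
]


@dataclass(frozen=True)
class BirthRecord:
    """One index birth with its order and the sex split of earlier siblings."""

    birth_order: int
    sex: str
    n_prior_sons: int
    n_prior_daughters: int
    age_years: Optional[int] = None
    adopted_flag: bool = False
    multifetal_flag: bool = False


@dataclass
class Family:
    """A mother and her ordered births, with eligibility bookkeeping."""

    family_id: str
    mother_ethnicity: str
    mother_birth_country: str
    generation: str
    origin: Optional[str]
    country_of_residence: str
    census_year: int
    births: list[BirthRecord] = field(default_factory=list)
    status: str = "eligible"
    exclusion_reason: str = ""
    n_mothers: int = 1
    n_fathers: int = 1


class EligibilityRules(BaseModel):
    """Eligibility filters and the ethnicity → Asian-origin mapping.

    Defaults implement the study design: at most four children, all aged 14
    or under and living with their mother, no adopted children, no multifetal
    births, no single-father or same-sex-couple households.
    """

    max_children: int = Field(default=4, ge=1)
    max_child_age: int = 14
    exclude_adopted: bool = True
    exclude_multifetal: bool = True
    exclude_single_father: bool = True
    exclude_same_sex_couple: bool = True
    ethnicity_to_origin: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_MAP)
    )
    domestic_ethnicities: set[str] = Field(default_factory=lambda: set(DEFAULT_DOMESTIC))

    @field_validator("ethnicity_to_origin")
    @classmethod
    def _total_mapping(cls, v: dict[str, str]) -> dict[str, str]:
        for eth, origin in v.items():
            if not origin:
                raise ValueError(f"ethnicity {eth!r} maps to an empty origin")
        return v


def classify_generation(
    mother_birth_country: str,
    mother_ethnicity: str,
    country_of_residence: str,
    rules: EligibilityRules,
) -> tuple[str, Optional[str]]:
    """Classify a mother's diaspora generation and origin country.

    First generation: born in the Asian origin country her ethnicity maps to.
    Second generation: born in the country of residence with an ethnicity
    mapping to an Asian origin. Domestic: local ethnicity born in the country
    of residence (the comparator population). Everything else — including
    mothers born in the origin country but of nonlocal ethnicity — is
    ``other`` and stratified out.
    """
    origin = rules.ethnicity_to_origin.get(mother_ethnicity)
    if origin is not None:
        if mother_birth_country == origin:
            return "first", origin
        if mother_birth_country == country_of_residence:
            return "second", origin
        return "other", origin
    if (
        mother_ethnicity in rules.domestic_ethnicities
        and mother_birth_country == country_of_residence
    ):
        return "domestic", country_of_residence
    if mother_ethnicity not in rules.domestic_ethnicities:
        logger.warning("unmapped ethnicity %r classified as 'other'", mother_ethnicity)
    return "other", None


def assign_birth_orders(
    children: Iterable[Union[PersonRecord, dict]],
) -> list[BirthRecord]:
    """Order one mother's children by descending age and compute priors.

    Any two children sharing an integer age are flagged as suspected
    multifetal (the flag propagates to filtering; order among them is
    arbitrary but deterministic by person id).
    """
    rows = []
    for c in children:
        if isinstance(c, PersonRecord):
            rows.append((c.age_years, c.person_id, c.sex, c.adopted_flag))
        else:
            rows.append(
                (c["age_years"], c.get("person_id", ""), c["sex"],
                 bool(c.get("adopted_flag", False)))
            )
    rows.sort(key=lambda r: (-r[0], r[1]))
    ages = [r[0] for r in rows]
    dup_ages = {a for a in ages if ages.count(a) > 1}
    births: list[BirthRecord] = []
    sons = daughters = 0
    for order, (age, _pid, sex, adopted) in enumerate(rows, start=1):
        births.append(
            BirthRecord(
                birth_order=order,
                sex=sex,
                n_prior_sons=sons,
                n_prior_daughters=daughters,
                age_years=age,
                adopted_flag=adopted,
                multifetal_flag=age in dup_ages,
            )
        )
        if sex == "female":
            daughters += 1
        else:
            sons += 1
    return births


def apply_filters(family: Family, rules: EligibilityRules) -> Family:
    """Return a copy of ``family`` with status and exclusion reason set.

    The first matching rule in the fixed order wins; birth data are never
    mutated. Age rules are skipped when births carry no ages (history mode).
    """
    reason = ""
    if family.n_mothers == 0:
        if family.n_fathers >= 2 and rules.exclude_same_sex_couple:
            reason = "same_sex_couple"
        elif family.n_fathers == 1 and rules.exclude_single_father:
            reason = "single_father"
        elif family.n_fathers == 0:
            reason = "no_mother"
    if not reason and rules.exclude_adopted and any(b.adopted_flag for b in family.births):
        reason = "adopted"
    if not reason and rules.exclude_multifetal and any(
        b.multifetal_flag for b in family.births
    ):
        reason = "multifetal"
    if not reason and len(family.births) > rules.max_children:
        reason = "family_size"
    if not reason and any(
        b.age_years is not None and b.age_years > rules.max_child_age
        for b in family.births
    ):
        reason = "child_over_age"
    return dataclasses.replace(
        family,
        status="excluded" if reason else "eligible",
        exclusion_reason=reason,
    )


def _as_roster_frame(roster) -> pd.DataFrame:
    if isinstance(roster, pd.DataFrame):
        return roster
    return roster_frame(list(roster))


def reconstruct_families(
    roster,
    rules: Optional[EligibilityRules] = None,
) -> list[Family]:
    """Reconstruct one Family per household from a census-style roster.

    ``roster`` may be a DataFrame or an iterable of :class:`PersonRecord`.
    Households without any child are dropped silently; households with more
    than one mother are an input error; duplicate person ids are an input
    error. Filtering is NOT applied here — every returned family still has
    status ``eligible`` except households without a mother, which are already
    excluded (single_father / same_sex_couple / no_mother).
    """
    rules = rules or EligibilityRules()
    df = _as_roster_frame(roster)
    if df.empty:
        return []
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"duplicate person_id {dup!r}")
    if df["household_id"].isna().any():
        raise ValueError("row with missing household_id")

    families: list[Family] = []
    # single sorted pass keeps this linear even for multi-hundred-thousand-row
    # rosters (pandas per-group iteration would dominate the pipeline)
    df = df.sort_values(["household_id", "person_id"], kind="mergesort")
    gen_cache: dict[tuple[str, str, str], tuple[str, Optional[str]]] = {}

    def _flush(hid, mothers, fathers, children):
        if len(mothers) > 1:
            raise ValueError(f"household {hid!r} has {len(mothers)} mother rows")
        if not children:
            return  # childless household: not part of any denominator
        births = assign_birth_orders(children)
        anchor = mothers[0] if mothers else (fathers[0] if fathers else children[0])
        if not mothers:
            fam = Family(
                family_id=str(hid),
                mother_ethnicity="",
                mother_birth_country="",
                generation="other",
                origin=None,
                country_of_residence=str(anchor["country_of_residence"]),
                census_year=int(anchor["census_year"]),
                births=births,
                n_mothers=0,
                n_fathers=len(fathers),
            )
            # no-mother households are excluded already at reconstruction
            fam = apply_filters(fam, rules)
        else:
            m = mothers[0]
            key = (str(m["birth_country"]), str(m["ethnicity"]),
                   str(m["country_of_residence"]))
            if key not in gen_cache:
                gen_cache[key] = classify_generation(key[0], key[1], key[2], rules)
            generation, origin = gen_cache[key]
            fam = Family(
                family_id=str(hid),
                mother_ethnicity=str(m["ethnicity"]),
                mother_birth_country=str(m["birth_country"]),
                generation=generation,
                origin=origin,
                country_of_residence=str(m["country_of_residence"]),
                census_year=int(m["census_year"]),
                births=births,
                n_mothers=1,
                n_fathers=len(fathers),
            )
        families.append(fam)

    current = None
    mothers: list[dict] = []
    fathers: list[dict] = []
    children: list[dict] = []
    for row in df[["household_id", "person_id", "role", "sex", "age_years",
                   "ethnicity", "birth_country", "adopted_flag", "census_year",
                   "country_of_residence"]].itertuples(index=False):
        hid = row.household_id
        if hid != current:
            if current is not None:
                _flush(current, mothers, fathers, children)
            current, mothers, fathers, children = hid, [], [], []
        rec = row._asdict()
        if row.role == "mother":
            mothers.append(rec)
        elif row.role == "father":
            fathers.append(rec)
        else:
            children.append(rec)
    if current is not None:
        _flush(current, mothers, fathers, children)
    return families


def ingest_birth_history(
    rows: pd.DataFrame,
    rules: Optional[EligibilityRules] = None,
) -> list[Family]:
    """Assemble families from a direct birth-history table.

    Orders are taken as stated and validated: per mother they must be the
    contiguous sequence 1..k (a duplicate or a gap is an input error).
    Prior-sex counts are recomputed from the sequence. Eligibility rules are
    applied, minus age-based ones (the format has no ages) and household-
    structure ones (no parent rows).
    """
    rules = rules or EligibilityRules()
    families: list[Family] = []
    if rows.empty:
        return families
    for mid, grp in rows.sort_values(["mother_id", "birth_order"]).groupby(
        "mother_id", sort=False
    ):
        orders = list(grp["birth_order"])
        if len(set(orders)) != len(orders):
            raise ValueError(f"duplicate (mother_id, birth_order) for mother {mid!r}")
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError(f"birth orders for mother {mid!r} are not contiguous from 1")
        births = []
        sons = daughters = 0
        for order, sex in zip(orders, grp["sex"]):
            births.append(
                BirthRecord(birth_order=order, sex=sex, n_prior_sons=sons,
                            n_prior_daughters=daughters)
            )
            if sex == "female":
                daughters += 1
            else:
                sons += 1
        first = grp.iloc[0]
        generation, origin = classify_generation(
            str(first["mother_birth_country"]), str(first["mother_ethnicity"]),
            str(first["country_of_residence"]), rules,
        )
        fam = Family(
            family_id=str(mid),
            mother_ethnicity=str(first["mother_ethnicity"]),
            mother_birth_country=str(first["mother_birth_country"]),
            generation=generation,
            origin=origin,
            country_of_residence=str(first["country_of_residence"]),
            census_year=int(first["census_year"]),
            births=births,
        )
        families.append(apply_filters(fam, rules))
    return families


def build_families(roster, rules: Optional[EligibilityRules] = None) -> list[Family]:
    """Reconstruct then filter: the full roster-mode path."""
    rules = rules or EligibilityRules()
    return [apply_filters(f, rules) for f in reconstruct_families(roster, rules)]


def families_to_frame(families: Iterable[Family]) -> pd.DataFrame:
    """Flatten families to one row per birth (the families-file interface)."""
    rows = []
    for f in families:
        for b in f.births:
            rows.append(
                (f.family_id, f.status, f.exclusion_reason, f.country_of_residence,
                 f.census_year, f.mother_ethnicity, f.mother_birth_country,
                 f.generation, f.origin if f.origin is not None else "",
                 b.birth_order, b.sex,
                 b.age_years if b.age_years is not None else -1,
                 b.n_prior_sons, b.n_prior_daughters)
            )
    return pd.DataFrame(rows, columns=FAMILY_FRAME_COLUMNS)


def exclusion_audit(families: Iterable[Family]) -> dict[str, int]:
    """Counts per exclusion reason plus the eligible total."""
    audit = {"eligible": 0, **{r: 0 for r in EXCLUSION_ORDER}}
    for f in families:
        if f.status == "eligible":
            audit["eligible"] += 1
        else:
            audit[f.exclusion_reason] = audit.get(f.exclusion_reason, 0) + 1
    return audit
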