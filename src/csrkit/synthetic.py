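"""Synthetic census generator with a son-preference fertility model.

Families are simulated birth by birth. Each conception is female with
probability ``q0`` (the baseline female fraction absent any selection). In
contexts where prenatal selection operates, a conception of the targeted sex
is vetoed with probability ``s`` and replaced by a fresh conception in the
same context ("veto and redraw", the generative stand-in for a sex-selective
abortion followed by another pregnancy). Under this mechanism the conditional
sex ratio of the affected context has the closed form

    CSR = 1000 * (q0 / (1 - q0)) * (1 - s)   girls per 1000 boys,

which :func:`expected_csr` returns and which the test suite uses as the
ground-truth oracle. Whether a family attempts another birth is governed by
parity-progression probabilities that may depend on the current sex
composition (son-preference stopping rules); stopping rules alone never move
the CSR, which is the identifying property of the method.

The generator emits census-style household rosters (one row per person) and,
from the same simulated families, direct birth-history tables (one row per
birth), so both input modes of the reconstruction pipeline can be exercised
against known ground truth. Contaminant households (twins, adopted children,
single fathers, two-father couples, 5+-child families, children older than
14) are injected at configurable rates so every eligibility filter fires.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "PersonRecord",
    "StratumSpec",
    "ContaminantRates",
    "GeneratorConfig",
    "expected_csr",
    "generate_population",
    "emit_birth_history",
    "roster_frame",
]

ROSTER_COLUMNS = [
    "household_id",
    "person_id",
    "role",
    "sex",
    "age_years",
    "ethnicity",
    "birth_country",
    "adopted_flag",
    "census_year",
    "country_of_residence",
]

BIRTH_HISTORY_COLUMNS = [
    "mother_id",
    "country_of_residence",
    "census_year",
    "mother_ethnicity",
    "mother_birth_country",
    "birth_order",
    "sex",
]

TRUTH_COLUMNS = [
    "household_id",
    "birth_order",
    "sex",
    "age_years",
    "contaminants",
    "country_of_residence",
    "census_year",
    "mother_ethnicity",
    "mother_birth_country",
]


@dataclass(frozen=True)
class PersonRecord:
    """One census-roster row: a person with household linkage.

    Mirrors the fields a census extract would carry; nothing about true birth
    order or contaminant status appears here (that lives in the generator's
    side-channel truth table).
    """

    household_id: str
    person_id: str
    role: str  # mother | father | child
    sex: str  # female | male
    age_years: int
    ethnicity: str
    birth_country: str
    adopted_flag: bool
    census_year: int
    country_of_residence: str


class StratumSpec(BaseModel):
    """One population cell: residence country/year and mother's background.

    ``selection_prob`` (optional) overrides the config-level selection map
    for families in this stratum, so e.g. a domestic comparator stratum can
    be generated selection-free alongside a diaspora stratum.
    """

    country_of_residence: str
    census_year: int
    mother_ethnicity: str
    mother_birth_country: str
    n_families: int = Field(ge=0)
    selection_prob: Optional[dict[str, float]] = None


class ContaminantRates(BaseModel):
    """Per-family probabilities of each contaminant type (independent draws)."""

    twin: float = Field(default=0.0, ge=0.0, le=1.0)
    adopted: float = Field(default=0.0, ge=0.0, le=1.0)
    single_father: float = Field(default=0.0, ge=0.0, le=1.0)
    same_sex_couple: float = Field(default=0.0, ge=0.0, le=1.0)
    five_plus: float = Field(default=0.0, ge=0.0, le=1.0)
    overage_child: float = Field(default=0.0, ge=0.0, le=1.0)


def _context_key(parity: int, sons, daughters) -> str:
    return f"{parity},{sons},{daughters}"


#: Illustrative parity-progression defaults with a mild son-preference
#: stopping rule (families without a son progress more often). The paper-style
#: sources publish no fertility schedule, so these are labeled illustrative;
#: the CSR is invariant to them by construction.
DEFAULT_PARITY_PROGRESSION = {
    "1,1,0": 0.66,
    "1,0,1": 0.74,
    "2,0,2": 0.42,
    "2,*,*": 0.24,
    "3,0,3": 0.18,
    "3,*,*": 0.10,
    "4,*,*": 0.0,
}

DEFAULT_CONTAMINANTS = ContaminantRates(
    twin=0.01,
    adopted=0.005,
    single_father=0.01,
    same_sex_couple=0.002,
    five_plus=0.01,
    overage_child=0.01,
)


class GeneratorConfig(BaseModel):
    """Full parameterisation of the synthetic census.

    ``parity_progression`` and ``selection_prob`` are keyed by strings
    ``"parity,n_sons,n_daughters"`` where either count may be the wildcard
    ``*``; exact keys take precedence over wildcards. Selection contexts with
    no entry have s = 0. ``selection_target_sex`` is the sex whose conceptions
    are vetoed (default female; per-context overrides support the
    after-a-first-son pattern seen in China, where second-born males are
    selected against).
    """

    n_families: int = Field(default=1000, ge=0)
    baseline_female_prob: float = 0.48718
    parity_progression: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PARITY_PROGRESSION)
    )
    selection_prob: dict[str, float] = Field(default_factory=dict)
    selection_target_sex: Literal["female", "male"] = "female"
    selection_target_overrides: dict[str, Literal["female", "male"]] = Field(
        default_factory=dict
    )
    contaminant_rates: ContaminantRates = Field(
        default_factory=lambda: DEFAULT_CONTAMINANTS.model_copy()
    )
    strata: Optional[list[StratumSpec]] = None
    one_child_policy: bool = False
    policy_exempt_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    seed: int

    @field_validator("baseline_female_prob")
    @classmethod
    def _q0_open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("baseline_female_prob must lie strictly in (0, 1)")
        return v

    @field_validator("parity_progression", "selection_prob")
    @classmethod
    def _probs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for key, p in v.items():
            parts = key.split(",")
            if len(parts) != 3:
                raise ValueError(f"malformed context key {key!r}; want 'parity,sons,daughters'")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for context {key!r} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _progression_covers_parities(self) -> "GeneratorConfig":
        for parity in range(1, 5):
            keys = [k for k in self.parity_progression if k.startswith(f"{parity},")]
            if not keys:
                raise ValueError(f"parity_progression has no entry for parity {parity}")
        return self

    def resolved_strata(self) -> list[StratumSpec]:
        if self.strata:
            return list(self.strata)
        return [
            StratumSpec(
                country_of_residence="Canada",
                census_year=2016,
                mother_ethnicity="Indian",
                mother_birth_country="India",
                n_families=self.n_families,
            )
        ]


def expected_csr(q0: float, s: float) -> float:
    """Closed-form CSR of the veto-and-redraw model, girls per 1000 boys.

    A conception is female with probability ``q0``; a conception of the
    targeted (female) sex is vetoed and redrawn with probability ``s``, so
    accepted births are female with probability q0(1-s)/(1-q0*s) and the
    female/male ratio is (q0/(1-q0))*(1-s). Exact, unrounded.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie strictly in (0, 1)")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    return 1000.0 * (q0 / (1.0 - q0)) * (1.0 - s)


def _lookup(table: dict[str, float], parity: int, sons: int, daughters: int, default=0.0):
    exact = table.get(_context_key(parity, sons, daughters))
    if exact is not None:
        return exact
    wild = table.get(_context_key(parity, "*", "*"))
    if wild is not None:
        return wild
    return default


@dataclass
class _SimFamily:
    """Internal ground truth for one simulated family."""

    household_id: str
    stratum: StratumSpec
    births: list[tuple[str, int]] = field(default_factory=list)  # (sex, age)
    contaminants: list[str] = field(default_factory=list)
    adopted_child_index: Optional[int] = None
    twin_of_index: Optional[int] = None  # twin contaminant duplicates this birth
    twin_sex: Optional[str] = None


def _draw_birth_sex(rng: random.Random, cfg: GeneratorConfig, parity: int,
                    sons: int, daughters: int,
                    selection: Optional[dict[str, float]] = None) -> str:
    """One accepted birth under veto-and-redraw in the given context."""
    q0 = cfg.baseline_female_prob
    sel_map = selection if selection is not None else cfg.selection_prob
    s = _lookup(sel_map, parity, sons, daughters)
    key = _context_key(parity, sons, daughters)
    target = cfg.selection_target_overrides.get(key, cfg.selection_target_sex)
    while True:
        sex = "female" if rng.random() < q0 else "male"
        if s > 0.0 and sex == target and rng.random() < s:
            continue  # vetoed conception; redraw in the same context
        return sex


def _assign_ages(rng: random.Random, n_births: int) -> list[int]:
    """Strictly decreasing integer ages; first-born uniform on [n-1, 14]."""
    first = rng.randint(n_births - 1, 14)
    ages = [first]
    for i in range(1, n_births):
        remaining_below = n_births - 1 - i
        avail = ages[-1] - remaining_below
        gap = rng.randint(1, min(4, avail)) if avail > 1 else 1
        ages.append(ages[-1] - gap)
    return ages


def _simulate(config: GeneratorConfig) -> list[_SimFamily]:
    rng = random.Random(config.seed)
    rates = config.contaminant_rates
    families: list[_SimFamily] = []
    idx = 0
    for stratum in config.resolved_strata():
        selection = stratum.selection_prob  # None -> config-level map
        for _ in range(stratum.n_families):
            idx += 1
            fam = _SimFamily(household_id=f"H{idx:07d}", stratum=stratum)
            exempt = (not config.one_child_policy) or (
                rng.random() < config.policy_exempt_fraction
            )
            sons = daughters = 0
            parity = 1
            sexes: list[str] = []
            while True:
                sex = _draw_birth_sex(rng, config, parity, sons, daughters, selection)
                sexes.append(sex)
                if sex == "female":
                    daughters += 1
                else:
                    sons += 1
                p_next = _lookup(config.parity_progression, parity, sons, daughters)
                if config.one_child_policy and not exempt:
                    p_next = 0.0  # one-child restriction gates all progression
                parity += 1
                if parity > 5 or rng.random() >= p_next:
                    break
            # contaminants, each an independent draw
            if rng.random() < rates.five_plus:
                fam.contaminants.append("five_plus")
                while len(sexes) < 5:
                    sex = _draw_birth_sex(rng, config, len(sexes) + 1, sons,
                                          daughters, selection)
                    sexes.append(sex)
                    if sex == "female":
                        daughters += 1
                    else:
                        sons += 1
            ages = _assign_ages(rng, len(sexes))
            if rng.random() < rates.overage_child:
                fam.contaminants.append("overage_child")
                ages[0] = rng.randint(15, 17)  # oldest pushed past the age cap
            fam.births = list(zip(sexes, ages))
            if rng.random() < rates.twin:
                fam.contaminants.append("twin")
                fam.twin_of_index = rng.randrange(len(sexes))
                # dizygotic: twin sex independent, no selection applied
                fam.twin_sex = (
                    "female" if rng.random() < config.baseline_female_prob else "male"
                )
            if rng.random() < rates.adopted:
                fam.contaminants.append("adopted")
                fam.adopted_child_index = rng.randrange(len(sexes))
            if rng.random() < rates.single_father:
                fam.contaminants.append("single_father")
            elif rng.random() < rates.same_sex_couple:
                fam.contaminants.append("same_sex_couple")
            families.append(fam)
    return families


def _family_rows(fam: _SimFamily) -> list[PersonRecord]:
    st = fam.stratum
    hid = fam.household_id
    rows: list[PersonRecord] = []
    oldest = max(age for _, age in fam.births)
    parent_age = oldest + 24
    single_father = "single_father" in fam.contaminants
    same_sex = "same_sex_couple" in fam.contaminants
    if not single_father and not same_sex:
        rows.append(
            PersonRecord(hid, f"{hid}_m", "mother", "female", parent_age,
                         st.mother_ethnicity, st.mother_birth_country, False,
                         st.census_year, st.country_of_residence)
        )
    rows.append(
        PersonRecord(hid, f"{hid}_f1", "father", "male", parent_age + 2,
                     st.mother_ethnicity, st.mother_birth_country, False,
                     st.census_year, st.country_of_residence)
    )
    if same_sex:
        rows.append(
            PersonRecord(hid, f"{hid}_f2", "father", "male", parent_age + 3,
                         st.mother_ethnicity, st.mother_birth_country, False,
                         st.census_year, st.country_of_residence)
        )
    for i, (sex, age) in enumerate(fam.births):
        adopted = fam.adopted_child_index == i
        rows.append(
            PersonRecord(hid, f"{hid}_c{i + 1}", "child", sex, age,
                         st.mother_ethnicity, st.country_of_residence, adopted,
                         st.census_year, st.country_of_residence)
        )
        if fam.twin_of_index == i:
            rows.append(
                PersonRecord(hid, f"{hid}_c{i + 1}t", "child", fam.twin_sex, age,
                             st.mother_ethnicity, st.country_of_residence, False,
                             st.census_year, st.country_of_residence)
            )
    return rows


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[PersonRecord], pd.DataFrame]:
    """Generate a census-style roster plus a ground-truth side table.

    Returns ``(persons, truth)``. The roster contains only fields a census
    would have; ``truth`` holds one row per true birth with the family's
    contaminant labels ('' when clean), for validating reconstruction.
    Deterministic: same config (including seed) gives identical output.
    """
    persons: list[PersonRecord] = []
    truth_rows = []
    for fam in _simulate(config):
        persons.extend(_family_rows(fam))
        tags = "|".join(fam.contaminants)
        st = fam.stratum
        for order, (sex, age) in enumerate(fam.births, start=1):
            truth_rows.append(
                (fam.household_id, order, sex, age, tags,
                 st.country_of_residence, st.census_year,
                 st.mother_ethnicity, st.mother_birth_country)
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return persons, truth


def emit_birth_history(config: GeneratorConfig) -> pd.DataFrame:
    """Serialize the same simulated families as a direct birth-history table.

    One row per true birth (mother id, stratum fields, birth order, sex), the
    format a fertility survey with complete birth histories would provide.
    Adopted children are not births to the mother and never appear; a twin
    contaminant appears as an extra birth with the next order. Under the same
    seed the family-by-family sex sequences agree with the roster output.
    """
    rows = []
    for fam in _simulate(config):
        st = fam.stratum
        mid = f"{fam.household_id}_m"
        order = 0
        for i, (sex, _age) in enumerate(fam.births):
            order += 1
            rows.append((mid, st.country_of_residence, st.census_year,
                         st.mother_ethnicity, st.mother_birth_country, order, sex))
            if fam.twin_of_index == i:
                order += 1
                rows.append((mid, st.country_of_residence, st.census_year,
                             st.mother_ethnicity, st.mother_birth_country,
                             order, fam.twin_sex))
    return pd.DataFrame(rows, columns=BIRTH_HISTORY_COLUMNS)


def roster_frame(persons: list[PersonRecord]) -> pd.DataFrame:
    """Roster rows as a DataFrame in the canonical column order."""
    return pd.DataFrame([p.__dict__ for p in persons], columns=ROSTER_COLUMNS)
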