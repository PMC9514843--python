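"""Sex ratios and conditional sex ratios (CSRs).

The sex ratio is expressed as girls per 1000 boys: with Pf the proportion of
female births in a cell, CSR = (Pf/(1-Pf)) * 1000, which equals 1000·f/m on
the raw counts. The conditional sex ratio restricts the cell to births of a
given order following a specified sex composition of earlier siblings (e.g.
third births after two daughters) — the quantity that exposes prenatal sex
selection, because absent selection the sex of a birth is independent of the
sexes of earlier births.

Cells with fewer than 100 total births are suppressed (counts retained, no
ratio reported) to keep ratio estimates stable; the natural range absent
selection is 950–975 girls per 1000 boys.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .families import Family

__all__ = [
    "StratumKey",
    "CSREstimate",
    "NaturalRange",
    "sex_ratio",
    "conditional_counts",
    "conditional_count_frame",
    "estimate_csr",
    "deviation_from_natural",
    "csr_interval",
    "missing_female_births",
]

MIN_CELL_TOTAL = 100

COUNT_FRAME_COLUMNS = [
    "country_of_residence",
    "census_year",
    "mother_ethnicity",
    "mother_birth_country",
    "generation",
    "origin",
    "birth_order",
    "n_prior_sons",
    "n_prior_daughters",
    "females",
    "males",
]


@dataclass(frozen=True)
class StratumKey:
    """Which cell to count: stratum × birth order × prior composition.

    Any stratum field left as None acts as a wildcard.
    """

    birth_order: int
    prior_composition: tuple[int, int]  # (n_prior_sons, n_prior_daughters)
    country_of_residence: Optional[str] = None
    period: Optional[object] = None  # census year or pooled label
    mother_origin: Optional[str] = None
    generation: Optional[str] = None

    def __post_init__(self):
        sons, daughters = self.prior_composition
        if sons + daughters != self.birth_order - 1:
            raise ValueError(
                "prior_composition inconsistent with birth_order: "
                f"{sons}+{daughters} != {self.birth_order}-1"
            )


@dataclass(frozen=True)
class NaturalRange:
    """The band of sex ratios observed where prenatal selection is rare."""

    low: int = 950
    high: int = 975
    equivalent_male_ratio: float = 1.05  # informational: boys per girl


@dataclass(frozen=True)
class CSREstimate:
    """Counts, female proportion, and the (possibly suppressed) ratio."""

    f_count: int
    m_count: int
    total: int
    pf: float
    csr: Optional[int]
    suppressed: bool
    ci: Optional[tuple[float, float]] = None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sex_ratio(f_count: int, m_count: int) -> int:
    """Girls per 1000 boys, rounded to the nearest integer.

    Computed as 1000·f/m at full precision (algebraically identical to the
    Pf/(1-Pf) form) then rounded half away from zero, so it is invariant
    under rescaling both counts by any positive factor.
    """
    if f_count < 0 or m_count < 0:
        raise ValueError("counts must be non-negative")
    if m_count == 0:
        raise ValueError("sex ratio undefined with zero male births")
    return _round_half_away(1000.0 * f_count / m_count)


def conditional_counts(
    families: Iterable[Family], key: StratumKey
) -> tuple[int, int]:
    """(female, male) counts of the index births matching ``key``.

    Only eligible families contribute; each birth falls in exactly one
    (order, composition) cell. Empty cells give (0, 0).
    """
    f = m = 0
    sons, daughters = key.prior_composition
    for fam in families:
        if fam.status != "eligible":
            continue
        if key.country_of_residence is not None and fam.country_of_residence != key.country_of_residence:
            continue
        if key.period is not None and fam.census_year != key.period:
            continue
        if key.mother_origin is not None and fam.origin != key.mother_origin:
            continue
        if key.generation is not None and fam.generation != key.generation:
            continue
        for b in fam.births:
            if (
                b.birth_order == key.birth_order
                and b.n_prior_sons == sons
                and b.n_prior_daughters == daughters
            ):
                if b.sex == "female":
                    f += 1
                else:
                    m += 1
    return f, m


def conditional_count_frame(births: pd.DataFrame) -> pd.DataFrame:
    """Tally eligible births into (stratum × order × composition) cells.

    ``births`` is the one-row-per-birth families frame; only rows with
    status ``eligible`` are counted.
    """
    elig = births[births["status"] == "eligible"]
    if elig.empty:
        return pd.DataFrame(columns=COUNT_FRAME_COLUMNS)
    keys = COUNT_FRAME_COLUMNS[:9]
    tab = (
        elig.assign(is_f=(elig["sex"] == "female").astype(int))
        .groupby(keys, dropna=False, observed=True)
        .agg(females=("is_f", "sum"), total=("is_f", "size"))
        .reset_index()
    )
    tab["males"] = tab["total"] - tab["females"]
    return tab[COUNT_FRAME_COLUMNS].sort_values(keys).reset_index(drop=True)


def estimate_csr(
    f_count: int, m_count: int, min_total: int = MIN_CELL_TOTAL
) -> CSREstimate:
    """Point estimate with the small-cell suppression rule.

    Cells with fewer than ``min_total`` total births are suppressed: raw
    counts are retained (they are still needed for pooling) but no ratio is
    reported. A total of exactly ``min_total`` is reported.
    """
    if f_count < 0 or m_count < 0:
        raise ValueError("counts must be non-negative")
    total = f_count + m_count
    pf = f_count / total if total > 0 else float("nan")
    if total < min_total:
        return CSREstimate(f_count, m_count, total, pf, None, True)
    return CSREstimate(f_count, m_count, total, pf, sex_ratio(f_count, m_count), False)


def deviation_from_natural(csr: int, natural: NaturalRange = NaturalRange()) -> int:
    """Signed distance of a CSR from the natural band (0 if inside).

    Negative values (below 950) indicate selection against girls.
    """
    if csr is None:
        raise ValueError("deviation undefined for a suppressed estimate")
    if csr < natural.low:
        return csr - natural.low
    if csr > natural.high:
        return csr - natural.high
    return 0


def csr_interval(
    f_count: int, m_count: int, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for the CSR, girls per 1000 boys.

    A Wilson score interval on Pf mapped through p -> 1000·p/(1-p); the score
    form behaves sensibly at extreme Pf. Off by default in reporting — the
    study design deliberately reports point estimates only.
    """
    if f_count < 0 or m_count < 0:
        raise ValueError("counts must be non-negative")
    total = f_count + m_count
    if total == 0:
        raise ValueError("interval undefined with zero births")
    if f_count == 0 or m_count == 0:
        warnings.warn(
            "zero count in one sex: interval endpoint degenerates to 0 or inf",
            RuntimeWarning,
            stacklevel=2,
        )
    lo_p, hi_p = proportion_confint(f_count, total, alpha=1 - level, method="wilson")
    lo = 1000.0 * lo_p / (1.0 - lo_p)
    hi = 1000.0 * hi_p / (1.0 - hi_p) if hi_p < 1.0 else float("inf")
    return lo, hi


def missing_female_births(
    f_count: int, m_count: int, reference_csr: int = 950
) -> int:
    """Shortfall of observed girls against a reference ratio, clamped at 0.

    An extension for describing the size of a deficit; defaults to the
    conservative lower edge of the natural range.
    """
    if f_count < 0 or m_count < 0:
        raise ValueError("counts must be non-negative")
    expected_f = m_count * reference_csr / 1000.0
    return max(0, _round_half_away(expected_f) - f_count)
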