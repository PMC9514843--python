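# Methods

## The conditional sex ratio

All ratios are girls per 1000 boys. For a cell with `f` female and `m` male
births, the ratio is computed as `1000·f/m` at full floating precision and
rounded half away from zero to an integer. This is algebraically identical
to the `(Pf/(1−Pf))·1000` form on the female proportion Pf; computing from
raw counts rather than from a pre-rounded Pf avoids a ±1–2 rounding drift
(a two-decimal Pf of 0.47 yields 887 where the counts 1129/1267 yield 891).
Regression tests against published tables therefore allow ±1.

The **conditional** sex ratio (CSR) restricts the cell to births of one
order following one sex composition of earlier siblings. Its identifying
property: the sex of a conception is independent of the sexes of earlier
children, so *any* family-size behaviour — including son-preference stopping
rules and falling fertility — leaves the CSR inside the natural range of
950–975; only interference with the sex of the birth itself (in practice,
sex-selective abortion) moves it. The generator's property tests verify both
halves: stopping rules alone never shift the CSR, and selection shifts it by
exactly the closed form below.

**Suppression.** A cell is reported only when it holds at least
`min_total = 100` births (the boundary itself is reported). Suppression is a
pure function of the cell total; suppressed cells retain their raw counts
internally so that pooling remains exact, but render blank in outputs. The
threshold applies per reported cell: stratum × period × order × composition.

**Natural-range deviation** is the signed distance to the nearest edge of
[950, 975], zero inside. **Confidence intervals** (off by default, matching
the design choice of reporting point estimates against the natural range)
are Wilson score intervals on Pf mapped through `p ↦ 1000·p/(1−p)`; the
score form was chosen for its behaviour at extreme Pf, and a zero count in
either sex degenerates an endpoint to 0 or ∞ with a warning.
**Missing female births** is the clamped shortfall
`max(0, round(m·ref/1000) − f)` against a reference ratio defaulting to 950,
the conservative lower edge (962.5 or 975 are reasonable alternatives); it
is a descriptive extension, not an estimate of national totals.

## Family reconstruction

Roster mode implements the own-children method: within each household the
children are attached to the single mother row, ordered by strictly
decreasing integer age, and prior-son/daughter counts accumulated. Design
choices where the procedure is genuinely underdetermined:

- **Twin detection** is "equal integer age under the same mother". Census
  age in whole years cannot distinguish twins from siblings born under
  twelve months apart; the false-positive rate of that shortcut is accepted
  and such families are excluded wholesale.
- **Multifetal exclusion is family-level**, not birth-level: birth order
  among same-age siblings is unrecoverable, so dropping only the twin births
  would corrupt the prior-composition of later births.
- **Exclusion reasons are evaluated in a fixed order** — no_mother /
  single_father, same_sex_couple, adopted, multifetal, family_size (>4
  children), child_over_age (>14, inclusive cap at 14) — and each excluded
  family carries exactly the first matching reason, making audit counts
  reproducible. Adding any contaminant to an eligible family can only
  exclude it (tested as a monotonicity property).
- **Childless households are dropped silently**; they belong to no
  denominator.
- **Same-sex-couple households are represented as two-father households.**
  A two-mother household is rejected as an input error, because mother–child
  attachment would be ambiguous in every downstream step; the generator
  therefore also emits its same-sex contaminants as two-father homes.
- The **domestic comparator** passes through exactly the same filters as
  diaspora families.

Generation classification: a mother whose ethnicity maps to an Asian origin
country is *first* generation if born there and *second* if born in the
country of residence; local-ethnicity mothers born in the country of
residence are *domestic*; everything else — including origin-country-born
mothers of nonlocal ethnicity — is *other* and stratified out. Unmapped
ethnicities log a warning.

Birth-history mode trusts the stated orders (validated to be contiguous from
1 per mother, duplicates and gaps are input errors), recomputes prior-sex
counts, and skips age- and household-structure-based filters, which that
format cannot express. On contaminant-free synthetic data the two modes
produce identical conditional count tables (tested).

Counting is unweighted; the families file accepts an optional per-row weight
column that is currently ignored, since whether long-form census sampling
weights should enter the counts is an open question for real extracts.

## The synthetic census generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated.

- **Conception model.** Each conception is female with probability
  `q0 = 0.48718` by default, chosen so the no-selection ratio is
  `1000·q0/(1−q0) = 950`, the lower edge of the natural range; configurable.
- **Selection: veto and redraw.** In a context (parity, prior sons, prior
  daughters) with selection probability `s`, a conception of the targeted
  sex (default female; per-context overrides allow targeting males, the
  after-a-first-son pattern reported inside China) is discarded with
  probability `s` and redrawn in the same context. Accepted births are then
  female with probability `q0(1−s)/(1−q0·s)` and the cell's CSR is exactly
  `1000·(q0/(1−q0))·(1−s)` — the closed form behind every recovery test.
  This mechanism mirrors an abortion followed by another pregnancy and makes
  the implied selection probability recoverable as `ŝ = 1 − CSR/CSR₀`.
- **Parity progression.** The probability of attempting another birth after
  each parity 1–4 may depend on the current sex composition; defaults are a
  mild son-preference stopping rule (e.g. 0.74 after a first daughter vs
  0.66 after a first son). No fertility schedule is published for any of the
  study populations, so these defaults are **illustrative only**; the CSR is
  invariant to them by construction, and the tests exploit that.
- **One-child-policy mode** gates all progression past parity 1 for a
  non-exempt fraction of families (exempt fraction configurable),
  reproducing a design where second births are observed only in exempted
  groups.
- **Ages.** First-born age is uniform on [children−1, 14]; sibling gaps are
  integer, ≥1 and ≤4 years; twins share an age. This guarantees birth order
  is recoverable from age alone except for deliberate twin contaminants. The
  over-age contaminant sets the oldest child to 15–17.
- **Contaminants** (twin pair with independently drawn sexes, so both same-
  and dual-sex twins occur; adopted flag on one child; single-father and
  two-father households; growth to 5 children; an over-age child) are
  independent per-family draws; default rates (0.2–1%) are modest so the
  default population exercises every filter without dominating it. A family
  cannot be both single-father and same-sex.
- **Strata** carry (country, census year, mother ethnicity, mother birth
  country) and a family count; a stratum may override the selection map,
  letting one run hold a selection-free domestic comparator next to a
  diaspora stratum, as in the packaged demo.
- **Ground truth** (true birth order, sexes, contaminant labels) is written
  to a side table only; the roster carries nothing a census would not.
- **Determinism:** one `random.Random(seed)` stream drives the whole
  simulation, and the roster and birth-history emitters serialize the same
  simulated families, so fixed seed + config gives byte-identical files and
  family-by-family agreement between the two output modes. In birth-history
  output, adopted children are omitted (they are not births to the mother)
  and a twin appears as an extra birth at the next order; the roster/history
  equivalence contract is stated for contaminant-free configurations.

What the generator does *not* emulate: real marginal fertility rates,
migration and intermarriage dynamics, child mortality, age heaping, or
underreporting of girls. Passing recovery tests therefore shows the
pipeline's arithmetic and reconstruction are correct under the model's
assumptions, not that real census extracts are free of those artefacts.

## Reporting

Years pool into contiguous fixed-width windows anchored at the earliest year
(anchor configurable), labelled `YYYY–YYYY`; window 1 keeps bare year labels.
Pooling sums counts and conserves births exactly (property-tested). The
report is long-format, one row per stratum × period × order × composition
cell across *all* compositions present (orders 1–4), so cell totals sum to
the eligible-birth count — a conservation check the pipeline logs at run
time along with the seed, a config hash, and per-stage record counts.

## Problem sizes in the test suite

Closed-form recovery is tested at 4,000 and 64,000 families (the 3σ band
shrinking as 1/√n), the pipeline-level recovery at 200,000 families, path
equivalence at 20,000, and the brute-force veto-and-redraw oracle at 10⁶
conceptions; these sizes put the Monte-Carlo 3σ bands at a few points to a
few tens of points on the ratio scale, tight enough to detect an off-by-one
in prior-composition bookkeeping. All stochastic tests are fixed-seed.

## Known limitations

- Integer-age twin detection misclassifies closely spaced siblings (above).
- True same-age non-twin siblings, if any passed the twin screen, have no
  principled ordering; they are flagged rather than ordered by guess.
- Suppressed cells below 100 births are never reported even when pooling
  could rescue them only partially; choose the pooling window first.
- The missing-female count is a within-cell description; it must not be
  summed into national totals, which require population-level modelling out
  of scope here.
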