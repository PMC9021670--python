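# Methods

## Problem and data model

Hospitalizations of nursing-home residents carry substantial iatrogenic
risk, and a share of them is judged avoidable if optimal structural and
nursing conditions were in place. The package operationalizes the
identification of *nursing home-sensitive conditions* in three coupled
stages: descriptive claims analysis, expert consensus measurement, and
health-economic extrapolation.

The unit of analysis is the 3-character ICD-10-GM discharge diagnosis.
Claims arrive pre-aggregated per insurer (`InsurerClaimsTable`): case
counts and mean cost per case by code, resident counts by age band ×
gender, and hospitalized-person counts by gender. No person-level records
exist anywhere in the pipeline.

## Claims aggregation

Insurer tables are pooled by summing case counts and case-weighting mean
costs; the pooled mean for a code therefore always lies inside the span
of the contributing insurer means, and pooling is exactly
order-invariant. The *frequency threshold* (default 0.1%) retains codes
whose case share exceeds the threshold. The default scope is
**per-insurer**: the filter runs before pooling and a code survives if
it passes in any one insurer. This is the only reading consistent with
the pooled study table, which retains a code whose pooled share is
0.095% — pooled-scope filtering is available as an option. The
denominator defaults to residents ("population"); hospitalizations can
be selected instead, as the source description does not fully determine
it.

Ranking sorts by cases descending with lexicographic code tie-break (the
source is silent on ties; determinism is required). Share percentages
are computed unrounded and displayed at 2 decimals. Codes below the
threshold are pooled into a *remainder* row whose mean cost is carried
as provided rather than recomputed, because the printed remainder mean
is internally inconsistent with the printed cost totals; the fixture
additionally stores the remainder *total* cost implied by the difference
of the two printed totals, which the cost aggregates use
(`validate_fixtures` reports the inconsistency as a warning).

Demographic summaries report, per gender and overall: the
hospitalized-person proportion (hospitalized persons / residents), the
hospitalization ratio (hospitalizations / hospitalized persons; null
when nobody was hospitalized), and the annual incidence
(hospitalizations / residents), which factorizes as proportion × ratio.
The printed per-gender hospitalization counts do not sum to the printed
total, so the summary accepts the total as an explicit argument.

## Delphi rating statistics

Ratings live on a 0–100 scale in 5-point steps; a missing rating
requires a comment and is excluded from every statistic (`n_valid` is
reported per code). Per code and round the summary holds the sample
median (mean of the central pair for even n), the quartiles, the
12.5th/87.5th percentiles, the *central-75% dispersion width*
`width75 = p87.5 − p12.5`, and the standard deviation (ddof = 1).

**Percentile interpolation.** Printed fractional percentile values do
not unambiguously identify one convention, so two are implemented and
selectable everywhere:

- `weibull` (default): weighted average at rank `(n+1)p` — R type 6, the
  default of common social-science statistics packages;
- `linear`: weighted average at `(n−1)p + 1` — R type 7, the numpy
  default.

Classification outcomes on panels engineered to the printed dispersion
are identical under both conventions (tested), so the choice does not
affect the study results.

**Round-transition rules.** A code is dropped after round 1 when ≥ 75%
of valid ratings are exactly zero (inclusive cutoff). Two clinically
similar codes (similarity is expert input, never computed) merge when
their medians differ by at most 5 points **and** both interquartile
limits are strictly less than 10 points apart; merged codes pool their
raw ratings before re-summarizing. On the study data neither rule fired.

**Subgroup comparisons** use the tie-corrected Kruskal–Wallis H with a
chi-square reference (groups − 1 df), computed independently for
specialty, gender and age band, each requiring ≥ 2 groups with ≥ 2
valid ratings; no multiple-testing correction is applied, matching the
source analysis. A pooled sample with zero variance returns H = 0,
p = 1 (no evidence of group differences) rather than the undefined
tie-corrected statistic.

**Stability** between rounds reports per-code absolute median
differences, counts at the 5- and 10-point levels, and mean IQR width
per round.

## Consensus classification

After round 2 each code takes exactly one route (the three routes
partition any code set):

| route | rule |
|---|---|
| direct | median ≥ 75 **and** width75 ≤ 15 |
| excluded | p87.5 < 75 |
| workshop | otherwise (75 ∈ [p12.5, p87.5], endpoints inclusive) |

All boundaries are inclusive; this is forced by published rows sitting
exactly on them (width exactly 15 → direct; p87.5 exactly 75 →
workshop). Direct codes keep their round-2 median as the final
avoidability; workshop codes take the consented value or remain
unflagged when consent was not reached; excluded codes are retained
unflagged for auditability. Workshop deliberation itself is human input
(an override hook for direct codes exists but defaults off, since the
workshop corroborated rather than changed direct values). The final
flag requires avoidability ≥ 70 (inclusive — a code consented at
exactly 70 is on the list) and a disease-category assignment, which is
a static lookup shipped as a fixture, not inferred from ICD chapters.

## Extrapolation

The extrapolation factor is the exact ratio national/sample population
(818,289 / 242,236 ≈ 3.37807), never rounded. Per code, total cost =
cases × mean cost; avoidable cases and cost multiply by the consented
avoidability proportion. Totals are formed per scope (all codes /
117 included codes / flagged codes) and level (sample / national =
sample × factor) at full precision; rounding to whole cases and euros
happens only at report rendering. Under this discipline the national
case totals reproduce the published figures exactly. The published
*avoidable-case* pair (65,133 sample; 219,955 national) is mutually
inconsistent under any single factor (65,133 × factor ≈ 220,024), so
the original per-code rounding path is unrecoverable; the package's
full-precision computation lands within 0.03% of the sample figure and
within 10⁻⁵ of the national one, and tests check both at 0.1%. Cost
totals are reconstructed from per-code mean costs printed in whole
euros, giving a documented reconstruction error of about 10⁻⁵
(≤ ~0.02%). No uncertainty intervals are produced; the source provides
none.

## ACS comparison

An ambulatory care-sensitive catalogue is a list of groups of 3- and
4-digit codes with optional group-level preventability; *core* groups
require preventability ≥ 85%. Overlap of a 3-digit code is `full` when
the code itself is a member, `partial` when only 4-digit children are
(strict reading of "partly"), `none` otherwise; adding members can only
promote a code along none → partial → full. When a code's children span
several groups, the first group in catalogue order is matched and
logged. Preventability differences (nursing-home minus group estimate)
are computed only for codes with a matched estimated group; others are
skipped with a log note. The published 258-condition catalogue is not
redistributed — the module defines the file format and the shipped
comparison figures in the transcription are documentation, not test
targets.

## Synthetic data generator

The generator defines the study conditions for testing: a four-group
panel (31 primary-care, 34 hospital-specialist, 31 nursing, 11 research
experts — the round-1 composition), ratings drawn from
`N(μ + group offset, σ)`, rounded half-up to the 5-point grid and
clipped to [0, 100]; round 2 replaces each draw by
`λ · median₁(code) + (1−λ) · fresh draw` with default shrinkage λ = 0.8,
reproducing the observed pattern of stable medians with collapsing
dispersion. Default rating noise σ = 10 and missing rate 1% are chosen
as realistic for a professional panel rating on a coarse grid; they are
not estimated from data. Claims tables draw multinomial case counts
over power-law-weighted codes (heavier tails concentrate the top code),
log-normal mean costs (log-mean 8.2 ≈ €3,600, log-sd 0.4), an annual
incidence of 0.79 cases per resident and an age/gender profile skewed
like a nursing-home population. A single root seed derives
per-component, per-code substreams (numpy `SeedSequence` spawn keys), so
identical seeds give identical output and adding codes does not perturb
existing draws.

What the generator does *not* emulate: clinically meaningful per-ICD
priors, cost correlation across codes, expert attrition between rounds,
or insurer-level plausibility exclusions (only their aggregated result).
Passing recovery tests therefore show that the rules behave correctly on
data with the designed statistical structure, not that the published
expert judgments would be reproduced by a new panel.

## Problem sizes and numerical choices

Fixture-based computations run on the full transcribed tables (117
codes, 58 flagged). Simulation-based tests use 200 seeded replicates of
3-code panels at full panel size for route recovery, and smaller designs
elsewhere; these sizes give binomial noise well below the 95% recovery
margin being tested. Ties in ranking break lexicographically;
discretization rounds half-up; all rule comparisons are applied to
unrounded values and display rounding is confined to writers.

## Known limitations

- The transcription inherits three documented inconsistencies of the
  printed tables (remainder mean cost; per-gender hospitalization sum;
  ±1 in gender resident totals); `validate_fixtures` surfaces them as
  warnings and the affected aggregates use the internally consistent
  alternatives described above.
- Raw expert ratings of the study are not public; per-code rating-level
  statistics can only be validated against the printed summaries and on
  synthetic panels.
- The ACS comparison operates on user-supplied catalogues only.
- Costs are 2017 amounts; no inflation adjustment is applied.
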