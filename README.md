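# nhsc — nursing home-sensitive conditions

`nhsc` is a Python library for identifying **nursing home-sensitive
conditions**: hospital discharge diagnoses for which a large share of
admissions from nursing homes is judged avoidable under optimal structural
and nursing care conditions. It reimplements, as tested reusable
components, the analysis chain that combines

1. **claims aggregation** — pooling per-insurer aggregated discharge
   tables (3-character ICD-10-GM code, case count, mean cost per case,
   demographic strata) from statutory health insurers, with a 0.1%
   frequency threshold applied per insurer before pooling;
2. **Delphi consensus statistics** — per-code rating distributions
   (median, quartiles, the central-75% dispersion interval between the
   12.5th and 87.5th percentiles), round-transition rules
   (zero-consensus exclusion, similar-code merging), Kruskal–Wallis
   subgroup comparisons and between-round stability metrics;
3. **RAND/UCLA-style classification** — after round 2, a code is
   *directly eligible* when its median avoidability is ≥ 75% and the
   central-75% width is ≤ 15 points, *excluded* when the 87.5th
   percentile falls below 75%, and otherwise routed to a moderated
   *expert workshop*; workshop-consented and direct codes with final
   avoidability ≥ 70% form the condition list;
4. **national extrapolation** — sample cases and costs scaled by the
   population ratio (818,289 German nursing-home residents /
   242,236 sampled), with the avoidable burden weighted per code by the
   consented avoidability proportion;
5. **ACS comparison** — overlap of the list with ambulatory
   care-sensitive catalogues (full / partial via 4-digit children / none);
6. **synthetic data** — seeded generators for insurer tables, two-round
   rating panels with controllable consensus, noise and round-2
   shrinkage, and workshop outcomes, so every stage is testable with
   known ground truth.

The package ships plain-CSV transcriptions of the published pooled study
tables (demographics; the 117-row frequency/cost table with its
below-threshold remainder; round-2 rating summaries with workshop flags;
workshop outcomes; the disease-category grouping) and reproduces the
published results from them at run time.

## Worked example

```python
from collections import Counter
from nhsc import run_pipeline

result = run_pipeline()          # defaults to the shipped study fixtures
print(Counter(c.route for c in result.classifications))
print(len(result.nhs_codes), result.category_counts.size)
rep = result.extrapolation
print(round(rep.value("nhs", "national", "avoidable_cases")))
print(round(rep.value("nhs", "national", "avoidable_cost")))
```

prints

```
Counter({'excluded': 57, 'direct': 35, 'workshop': 25})
58 15
219955
768311796
```

Of the 117 frequent discharge diagnoses, 35 are directly eligible after
the second rating round, 25 go to the expert workshop (23 of which were
consented), and the final list holds 58 conditions in 15 disease
categories. Extrapolated nationally, those conditions carry about 220
thousand potentially avoidable admissions and roughly €768 million in
potentially avoidable hospital costs per year. (The cost figure is
reconstructed from per-code mean costs printed in whole euros, so the
last digits differ from a computation on unrounded source data; the
relative reconstruction error is about 10⁻⁵.)

The `examples/` directory has one short script per capability —
aggregation, panel summaries, classification, extrapolation, ACS
comparison, and a fully synthetic end-to-end run. A thin CLI mirrors the
pipeline stages: `nhsc aggregate | delphi | classify | extrapolate |
compare | simulate | run-all` (see `nhsc --help`).

## Layout

- `src/nhsc/` — library modules (`claims`, `delphi`, `consensus`,
  `extrapolation`, `acs`, `simulate`, `pipeline`, `io`, `fixtures`, `cli`)
  and `data/` fixtures
- `tests/` — unit, property (hypothesis) and acceptance tests with
  independent brute-force oracles
- `docs/methods.md` — model, rules, numerical choices and limitations
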