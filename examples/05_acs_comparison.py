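"""Compare the final list against an ambulatory care-sensitive catalogue.

The published ACS catalogue is not redistributable, so this example
builds a synthetic one in the same file format: groups of 3- and 4-digit
codes with group-level preventability estimates. Overlap is `full` when
the 3-digit code itself is a member, `partial` when only 4-digit children
are.
"""

from nhsc import AcsCatalogue, AcsGroup, overlap_summary, preventability_differences, run_pipeline

result = run_pipeline()
codes = result.nhs_codes

# synthetic catalogue: half the list as 3-digit members, a few child-only
catalogue = AcsCatalogue(
    [
        AcsGroup("g01", "synthetic diabetes group", ["E11"], 86.0, True),
        AcsGroup("g02", "synthetic hypertension group", ["I10", "I95.0"], 88.0, True),
        AcsGroup("g03", "synthetic respiratory group", ["J20", "J40", "J44.1"], 85.0, True),
        AcsGroup("g04", "synthetic non-core group", ["N30", "K21"], 70.0, False),
    ]
)

summary = overlap_summary(codes, catalogue, subset="all")
c = summary["counts"]
print(f"{len(codes)} nursing home-sensitive codes vs a {len(catalogue.members())}-member "
      "synthetic catalogue:")
print(f"  full {c['full']}, partial {c['partial']}, none {c['none']} "
      f"-> {summary['overlap_fraction']:.0%} at least partly ambulatory care-sensitive")

avoid = {r.icd3: float(r.final_avoidability)
         for r in result.consensus.itertuples() if r.nhs_flag}
diffs = preventability_differences(avoid, catalogue, subset="core")
print("\nPer-code difference (nursing-home minus ACS-group preventability):")
print(diffs.to_string(index=False))
print(f"range: {diffs['difference'].min():+.0f} to {diffs['difference'].max():+.0f} "
      "percentage points — the two settings judge avoidability differently.")
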