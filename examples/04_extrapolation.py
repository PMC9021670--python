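"""Extrapolate sample cases and costs to the national population.

Scales the pooled sample (242,236 residents) to all German nursing-home
residents (818,289 in 2017) and weights the 58 flagged conditions by
their consented avoidability to estimate the avoidable burden.
"""

from nhsc import run_pipeline

result = run_pipeline()
rep = result.extrapolation
print(f"Extrapolation factor: 818,289 / 242,236 = {rep.factor:.5f}\n")
print(rep.to_frame().to_string(index=False))
shares = result.shares.set_index(["scope", "denominator"])
print(
    f"\nThe {len(result.nhs_codes)} flagged conditions carry "
    f"{shares.loc[('nhs', 'all'), 'case_share_pct']:.2f}% of all hospital cases "
    f"({shares.loc[('nhs', 'included'), 'case_share_pct']:.2f}% of the 117 "
    "frequent conditions)."
)
print(
    "Avoidable nationally: "
    f"{rep.value('nhs', 'national', 'avoidable_cases'):,.0f} admissions and "
    f"EUR {rep.value('nhs', 'national', 'avoidable_cost'):,.0f} per year, "
    "if optimal care conditions were in place."
)
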