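"""Pool per-insurer discharge tables and rank diagnoses by frequency.

Builds three small synthetic insurer tables, applies the 0.1% frequency
threshold per insurer (the filter runs before pooling, so a code common
in one fund's population survives even if rare overall), and prints the
ranked pooled table with cumulative case shares.
"""

from nhsc import (
    ClaimsSimConfig,
    apply_frequency_threshold,
    generate_claims,
    merge_insurer_tables,
    rank_and_cumulate,
)

tables = generate_claims(
    ClaimsSimConfig(n_insurers=3, populations=[8000, 12000, 20000], n_codes=15, seed=7)
)
retained = apply_frequency_threshold(tables, threshold=0.001, scope="per_insurer")
pooled = merge_insurer_tables(tables)
agg = rank_and_cumulate(pooled, retained)

print(f"{len(tables)} insurers, {pooled.population:,} residents, "
      f"{pooled.total_cases:,} hospitalizations")
print(f"{len(retained)} of {len(pooled.rows)} codes exceed 0.1% of some "
      f"insurer's population; {agg.remainder_cases} cases in the remainder\n")
print(agg.rows.head(5).round(2).to_string(index=False))
print("\nEach row: pooled cases, case-weighted mean cost (EUR), share and "
      "cumulative share of all hospitalizations.")
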