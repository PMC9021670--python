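"""Classify the study's 117 conditions and build the final list.

Loads the transcribed round-2 summaries, routes each code (direct /
workshop / excluded), applies the workshop outcomes and the 70%
avoidability floor, and prints the resulting nursing home-sensitive list
grouped by disease category.
"""

from collections import Counter

from nhsc import apply_workshop, classify_round2, finalize_nhs_list
from nhsc.consensus import category_counts
from nhsc.fixtures import (
    load_category_map,
    load_round2_summaries,
    load_workshop_outcomes,
)

summaries = load_round2_summaries()
classifications = [classify_round2(s) for s in summaries]
routes = Counter(c.route for c in classifications)
print(f"{len(summaries)} conditions: {routes['direct']} direct, "
      f"{routes['workshop']} workshop, {routes['excluded']} excluded")

records = apply_workshop(classifications, load_workshop_outcomes())
category_map, labels = load_category_map()
final = finalize_nhs_list(records, category_map, min_avoidability=70)
flagged = final[final["nhs_flag"]]
print(f"Final list: {len(flagged)} nursing home-sensitive conditions "
      f"(>= 70% of admissions judged avoidable under optimal care)\n")
for cat_id, count in category_counts(final).items():
    codes = ", ".join(flagged.loc[flagged["category_id"] == cat_id, "icd3"])
    print(f"  {cat_id:>2}. {labels[cat_id][:60]:<60} {codes}")
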