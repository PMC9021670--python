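"""Summarize a synthetic two-round expert panel.

Generates ratings for three conditions with different true consensus
levels, then prints the per-code round statistics used by the
classification rules: median, central-75% dispersion interval
(12.5th-87.5th percentile) and its width, and the specialty-comparison
Kruskal-Wallis p-value. Round 2 shrinks toward the round-1 median, so
widths collapse while medians stay put.
"""

from nhsc import PanelSimConfig, generate_panel, round_stability, summarize_ratings

config = PanelSimConfig(
    true_mu=[90.0, 60.0, 20.0],
    sigma=10.0,
    group_offsets={"hospital_specialist": -5.0},  # clinicians rate slightly lower
    missing_rate=0.02,
    shrinkage=0.8,
    seed=11,
)
r1, r2, truth = generate_panel(config)

for rnd, ratings in ((1, r1), (2, r2)):
    print(f"Round {rnd}:")
    for s in summarize_ratings(ratings):
        print(
            f"  {s.icd3}: n={s.n_valid}, median={s.median:.0f}, "
            f"central-75% [{s.p12_5:.1f}, {s.p87_5:.1f}] width={s.width75:.1f}, "
            f"KW specialty p={s.kw_p_specialty:.3f}"
        )

rep = round_stability(summarize_ratings(r1), summarize_ratings(r2))
print(
    f"\nStability: mean IQR width {rep.mean_iqr_width_r1:.1f} -> "
    f"{rep.mean_iqr_width_r2:.1f}; {rep.n_within_5}/{len(rep.per_code)} medians "
    "moved at most 5 points between rounds."
)
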