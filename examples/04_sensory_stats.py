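"""Questionnaire statistics: opposed pairs, sign fractions, Wilcoxon, Kendall.

Simulates a cohort's acceptance scores with the score -> band-power
coupling switched on, then asks the question the physiological analysis
asks: over within-subject product pairs with opposed scores (difference
of at least five points), how often is the LF power higher for the
low-acceptance product?
"""

import numpy as np
import pandas as pd

from neuroorganoleptics.ecg_hrv import RRSeries, band_powers
from neuroorganoleptics.sensory_stats import (
    attach_feature_diffs,
    hedonic_summary,
    kendall_repeatability,
    nps_categorize,
    select_opposed_pairs,
    sign_fraction,
    wilcoxon_matrix,
)
from neuroorganoleptics.synthetic_session import draw_window_powers, simulate_rr, simulate_scores

MEANS = {"bar": 7.5, "cheese": 8.0, "cookie": 6.5, "milk": 3.0}
table = simulate_scores(30, 3, MEANS, score_sd=1.5, seed=3)

# Per-window features with coupling: low score -> higher LF/HF.
rng = np.random.default_rng(4)
rows = []
ga = table[table["question"] == "global_acceptance"]
for _, r in ga.iterrows():
    lf, hf = draw_window_powers(r["response"], 600, 400, coupling=0.5, rng=rng)
    rr, bt = simulate_rr(150, 70, lf, hf, seed=rng)
    f = band_powers(RRSeries(bt[1:], rr))
    rows.append({"subject": r["subject"], "session": r["session"], "product": r["product"],
                 "lf_power": f.lf_power, "hf_power": f.hf_power,
                 "lf_norm": f.lf_norm, "hf_norm": f.hf_norm})
features = pd.DataFrame(rows)

pairs = attach_feature_diffs(select_opposed_pairs(table), features)
print(f"opposed pairs (score difference >= 5): {len(pairs)}")
print(f"LF higher for the low-acceptance product in {sign_fraction(pairs, 'lf_power'):.0%}")
print(f"HF higher for the low-acceptance product in {sign_fraction(pairs, 'hf_power'):.0%}")

p, mask = wilcoxon_matrix(features, "lf_power", alpha=0.01)
print("\npairwise Wilcoxon p-values (LF), significant at p <= 0.01 marked *:")
for a in p.index:
    for b in p.columns:
        if a < b and not np.isnan(p.loc[a, b]):
            star = " *" if mask.loc[a, b] else ""
            print(f"  {a} vs {b}: {p.loc[a, b]:.2e}{star}")

milk = ga[ga["product"] == "milk"].pivot_table(index="subject", columns="session",
                                               values="response")
tau, pv, verdict = kendall_repeatability(milk[1], milk[2])
print(f"\nmilk, sessions 1 vs 2: Kendall tau={tau:.2f}, p={pv:.3f} -> {verdict}")

hist, desc = hedonic_summary(table, "cheese")
print("\ncheese per-session acceptance mean +- sd:")
print(desc.round(2).to_string(index=False))

nps = table[table["question"] == "nps_recommend"]["response"].map(nps_categorize)
print("\nNPS categories:", nps.value_counts().to_dict())
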