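"""Build a reaction flux map and compare a perturbed condition to control.

Every reaction event of a simulation becomes an edge (substrate, product,
enzyme) weighted by its count.  The normalized condition/control ratio
divides each edge's flux ratio by the ratio of total core-fucosylation
(FUT8) flux: values above 1 mark pathways the condition prefers.
"""

from glycosim import (
    make_scenario,
    normalized_flux_ratio,
    simulate_profile,
    top_reactions,
)

control_model = make_scenario("complex-4c", seed=0).ground_truth
condition_model = make_scenario("cog4-like", seed=0).model()

_, control = simulate_profile(control_model, 10_000, seed=2)
_, condition = simulate_profile(condition_model, 10_000, seed=2)

print("top 6 FUT8 reactions in the control (substrate -> product, events):")
for (sub, prod, _), count in top_reactions(control, "FUT8", k=6):
    print(f"  {sub:22s} -> {prod:26s} {count:5d}")

report = normalized_flux_ratio(condition, control, normalizing_enzyme="FUT8")
fut8 = report.rows[report.rows["enzyme"] == "FUT8"]
print(f"\ntotal FUT8 flux: condition {report.normalizer[0]}, "
      f"control {report.normalizer[1]}")
print("normalized condition/control FUT8 flux ratios:")
for _, row in fut8.sort_values("ratio", ascending=False).head(6).iterrows():
    print(f"  {row['substrate']:22s} -> {row['product']:26s} {row['ratio']:.2f}")

# Ratios > 1: that substrate keeps a larger share of the (reduced) core-
# fucosylation flux in the knockdown-like condition than in the control.
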