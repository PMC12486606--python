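"""Score one population's mean intakes under all three indices.

Builds a small hand-written intake profile (mean g/day per food group),
scores it under WISH, WISH 2.0 and the EAT-Lancet index, and prints the
raw totals alongside the min-max normalized values. The normalized
numbers are comparable across indices; the raw totals are not, because
the indices live on 0-130, 0-150 and 0-42 scales.
"""

from dietscore import (
    IntakeProfile,
    PopulationId,
    builtin_index,
    compute_index_score,
    min_max_normalize,
)

# A plausible European-style diet, g/day. Keys are component ids; the
# WISH red-meat component expects processed meat folded in, WISH 2.0
# expects it separated out.
base = {
    "whole_grains": 110.0,
    "vegetables": 240.0,
    "fruits": 180.0,
    "dairy": 260.0,
    "fish": 22.0,
    "legumes": 15.0,
    "nuts": 9.0,
    "unsaturated_fats": 28.0,
    "poultry": 38.0,
    "eggs": 19.0,
    "saturated_oils": 14.0,
    "added_sugar": 38.0,
    "potatoes": 85.0,
}
unprocessed_red, processed = 35.0, 22.0

profiles = {
    "WISH": {**base, "red_meat": unprocessed_red + processed},
    "WISH2.0": {
        **base,
        "red_meat": unprocessed_red,
        "processed_meat": processed,
        "alcoholic_beverages": 140.0,
    },
    "EAT-Lancet": {**base, "beef_lamb": 20.0, "pork": unprocessed_red + processed - 20.0},
}

print(f"{'index':<12}{'total':>8}{'max':>6}{'normalized':>12}")
for name, intakes in profiles.items():
    index = builtin_index(name)
    score = compute_index_score(IntakeProfile(PopulationId("Example"), intakes), index)
    norm = min_max_normalize(score.total, index)
    print(f"{name:<12}{score.total:>8.1f}{index.theoretical_max:>6.0f}{norm:>12.2f}")
print(
    "\nA normalized value of, say, 0.40 means the population sits 40% of the"
    "\nway from the theoretical worst diet to full adherence on that index."
)
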