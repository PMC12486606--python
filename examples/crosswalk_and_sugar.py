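"""Category crosswalks: red-meat routing and added-sugar estimation.

Shows how survey source categories become index components: the same
basket of meats is routed differently by each index (WISH folds
processed meat into red meat, WISH 2.0 keeps it separate, the
EAT-Lancet index routes by predominant species — sausages count as
pork), and sweetened products count toward added sugar only in
proportion to their added-sugar content.
"""

from dietscore import (
    MeatTag,
    SugarCoefficients,
    builtin_index,
    default_crosswalk,
    estimate_added_sugar,
    split_red_meat,
)

meats = {"beef": 30.0, "pork": 25.0, "sausages": 20.0, "ham": 12.0}
tags = {
    "beef": MeatTag("beef", processed=False),
    "pork": MeatTag("pork", processed=False),
    "sausages": MeatTag("pork", processed=True),
    "ham": MeatTag("pork", processed=True),
}

print(f"meat basket ({sum(meats.values()):.0f} g/day total):", meats)
for index_name in ("WISH", "WISH2.0", "EAT-Lancet"):
    routed = split_red_meat(meats, tags, index_name)
    pretty = ", ".join(f"{c}={g:.0f}" for c, g in sorted(routed.items()))
    print(f"  {index_name:<11} -> {pretty}")

coef = SugarCoefficients({"sweets": 0.45, "soft_drinks": 0.09})
basket = {"sweets": 40.0, "soft_drinks": 300.0}
sugar = estimate_added_sugar(basket, coef)
print(f"\nadded sugar from {basket}: {sugar:.1f} g/day")
cutoff = builtin_index("WISH2.0").rule("added_sugar").cutoff
print(f"added-sugar cut-off is {cutoff} g/day -> this basket scores "
      f"{'10' if sugar < cutoff else '0'} points")

xw = default_crosswalk("EAT-Lancet")
print(f"\npackaged EAT-Lancet crosswalk: {len(xw.entries)} entries, "
      f"ignores {sorted(xw.ignore)}")
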