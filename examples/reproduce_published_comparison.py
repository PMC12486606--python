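"""Re-derive the published 11-country index comparison from its totals.

Loads the frozen per-country totals of the published application (11
European countries, three indices, total/female/male strata), normalizes
them to each index's theoretical bounds and prints the cross-index
comparison: the ordinal EAT-Lancet index scores higher on average but
spreads less than the continuous WISH family, and women outscore men
everywhere.
"""

from dietscore import (
    Gender,
    NormalizedScore,
    PopulationId,
    builtin_index,
    gender_gap,
    min_max_normalize,
    summarize_scores,
    table1_fixture,
)

fixture = table1_fixture()

print(f"{'index':<12}{'mean total':>11}{'norm mean':>11}{'norm SD':>9}")
for name in ("EAT-Lancet", "WISH", "WISH2.0"):
    index = builtin_index(name)
    totals = fixture.totals(name)
    values = [
        NormalizedScore(PopulationId(c), index.name, min_max_normalize(t, index))
        for c, t in totals.items()
    ]
    summary = summarize_scores(values)
    mean_total = sum(totals.values()) / len(totals)
    print(f"{name:<12}{mean_total:>11.1f}{summary.mean:>11.2f}{summary.sd:>9.3f}")

strata = {
    PopulationId(c, g): fixture.value(c, "WISH2.0", g)
    for c in fixture.countries
    for g in (Gender.FEMALE, Gender.MALE)
}
gap = gender_gap(strata)
print(
    f"\nWISH 2.0 gender means: female {gap.mean_female:.1f}, male {gap.mean_male:.1f}; "
    f"women score higher in {gap.n_female_higher}/11 countries."
)
print(
    "\nThe EAT-Lancet index's higher normalized mean with a smaller SD shows its"
    "\ncoarser 0-3 scale compresses between-country differences; the 0-10 WISH"
    "\nscales discriminate dietary patterns more sharply."
)
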