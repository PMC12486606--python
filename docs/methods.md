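# Methods

## Scope and model

`dietscore` operates on population-level summary data: one mean intake
(g/day) per (country, gender stratum, food category). It does not model
individual-level intake distributions; all scores are functions of
stratum means, which is why strict components (processed meat ≤ 2–4
g/day, any alcohol) essentially always score zero on population means
even when many individuals would satisfy them. That granularity limit
is inherent to the input data, not to the implementation.

Three indices are implemented as data (an ordered list of components,
each with a scoring rule and its parameters) interpreted by a small
rule engine. The rule kinds are:

- **adequacy** — `10·(intake − lower)/(recommended − lower)`, clamped to
  [0, 10]. At `intake = lower` the score is 0; above `recommended` it
  stays at 10 with no over-consumption penalty, because the continuous
  indices define no upper term for these groups. Whether some adequacy
  groups should decline again at very high intakes is an open modelling
  question; the engine would accommodate it as a new rule kind.
- **moderation** — `10·[(upper − recommended) − (intake − recommended)]
  /(upper − recommended)`, clamped. Full points at or below
  `recommended`, zero at or above `upper`.
- **binary cut-off** — 10 strictly below the cut-off, 0 at or above it
  (saturated oils 11.8 g/day, added sugar 31 g/day). The orientation is
  exposed as a per-rule switch (`cutoff_orientation`) because the two
  possible readings reward opposite behaviours; the default rewards low
  intake, consistent with the zero-tolerance alcohol rule and with the
  index family's intent.
- **zero tolerance** — 10 only at zero intake. Intakes ≤ 1e-9 g/day
  count as zero to absorb float noise from crosswalk arithmetic.
- **ordinal band** — 0–3 over three strictly increasing thresholds,
  closed on the adherent side (`higher_is_better`: ≥ top threshold → 3;
  `lower_is_better`: ≤ bottom threshold → 3).

Boundary conventions (score at exactly a threshold) follow the clamped
formulas themselves wherever the formula is defined there, so the
piecewise pieces agree at their joints; the binary rule scores 0 exactly
at the cut-off. Totals are exact sums kept at full precision; rounding
(totals 1 d.p., normalized values 2 d.p., SDs 3 d.p.) happens only at
the reporting layer.

## Parameter provenance

Parameters fixed by the index definitions: whole grains 125 g/day
within 100–150 (Global Burden of Disease recommendation, used by WISH
and WISH 2.0 instead of the PHD value), the 11.8 and 31 g/day binary
cut-offs, the 2–4 g/day processed-meat range, and alcohol zero
tolerance. All remaining reference intakes are PHD-derived defaults
shipped in `data/indices.yaml` (vegetables 300 within 200–600, red meat
14 within 0–28, and so on at the 2500 kcal/day reference) and are meant
to be edited, not treated as authoritative.

The EAT-Lancet index's per-component band thresholds are not published
in a form this package can cite as printed numbers; the packaged
defaults derive each component's three thresholds from its PHD target
and range (quarter/half/full of the target for adequacy-type groups;
target/midpoint/upper for moderation-type groups). They are labelled as
package defaults in the YAML and are swappable without code changes.
Added-sugar coefficients (proportion of a category's grams counted as
added sugar) are likewise configuration; the packaged 0.45 (sweets) and
0.09 (soft drinks) are illustrative placeholders.

## Normalization and summaries

Cross-index comparison uses min-max normalization against each index's
*theoretical* bounds, so a value is interpretable as the fraction of the
worst-to-best range attained. Summaries use the sample (n−1) standard
deviation: with the 11-country regression fixture only the n−1
denominator reproduces the published SDs (0.059/0.128/0.111; the
population denominator would give 0.056/0.122/0.106). Rankings break
ties by ascending population id for determinism. Gender comparisons pair
female/male strata by country and report signed female-minus-male
differences; the `total` stratum is carried as its own enumeration level
because survey means for the whole population are not the average of the
gender strata.

## Crosswalk

Source categories map to components through weighted entries (weights
per source sum to ≤ 1; partial weights express that only a fraction of
a category's grams belongs to a component, as with added sugar or the
fat fraction of butter). Red-meat-family categories carry a predominant
species tag and a processed flag: WISH folds everything into red meat,
WISH 2.0 routes processed grams to its own component, and the
EAT-Lancet index routes by species (sausages and ham count as pork).
A single predominant species per category is used — no proportional
species splitting. Unmapped categories are reported (or rejected in
strict mode) rather than silently dropped.

## Clustering

Gower's coefficient averages range-normalized absolute differences
(numeric) and 0/1 mismatches (categorical) over the variables on which
a pair is comparable. Ranges are computed over the analyzed units;
variables with zero range carry no information for the analysis and are
dropped with a warning (on population means this routinely happens to
components that score identically everywhere, e.g. alcohol). A pair
sharing no comparable variable is an error.

Agglomeration applies Ward's objective to the raw Gower dissimilarities
via the Lance–Williams recurrence

```
d(ij,k) = [(nᵢ+nₖ)d(i,k) + (nⱼ+nₖ)d(j,k) − nₖ d(i,j)] / (nᵢ+nⱼ+nₖ)
```

without squaring — the standard "generalized Ward" practice for
non-Euclidean inputs, which minimizes the within-cluster increase of
the chosen dissimilarity rather than of variance. (scipy's `ward`
linkage assumes Euclidean input and operates on squared distances, so
it is not interchangeable; a test verifies that on squared Euclidean
input this implementation reproduces textbook Ward merge orders against
an exhaustive objective-recomputing oracle.) Equal-dissimilarity merge
candidates break ties by the lexicographically smallest (first-leaf,
second-leaf) pair, making results platform-independent. Ward's
recurrence preserves height monotonicity; the tree nonetheless flags
violations rather than assuming them away. O(n³) agglomeration is
deliberate — population-level analyses involve tens of units, not
thousands.

Cutting undoes the last k−1 merges; cluster labels are ordered by each
cluster's first leaf. Silhouette widths are computed directly from the
dissimilarity matrix (`a(i)` mean within-cluster, `b(i)` smallest mean
to another cluster, members of singleton clusters set to 0 by the usual
convention) and are cross-checked against scikit-learn's implementation
in the tests. The cut `k` is chosen as the silhouette-maximizing value
over a candidate range (smallest k on ties), with the merge-height
sequence returned for scree inspection; the silhouette-vs-scree
arbitration when they disagree is left to the analyst, as no formal
rule exists. Cluster-to-region agreement uses the adjusted Rand index,
which is 0 in expectation under chance and 1 at perfect concordance.

The pipeline runs five analyses: WISH 2.0 component points and
EAT-Lancet component points for the total population and stratified by
gender (units = country × gender), plus raw g/day category intakes for
the total population. All five feature tables are numeric; the
categorical Gower branch exists for mixed tables and is exercised by
tests.

## Synthetic data

The generator emulates the *structure* of a harmonized European survey
export, not any real survey's values. Four regional archetypes
(Mediterranean, Western, Eastern, Northern) define mean intakes over 20
source categories, chosen once as qualitative caricatures: the
Mediterranean archetype is rich in vegetables, fruit, fish, legumes and
vegetable oils; the Western in meat, dairy and sweetened products; the
Eastern in pork, potatoes and sugar; the Northern in whole grains and
dairy. Gender multipliers (men more meat, soft drinks and alcohol;
women more fruit and vegetables) are illustrative of commonly reported
patterns, not estimates.

Noise is multiplicative lognormal with a target coefficient of
variation (default 0.15, a plausible between-country spread within a
region): each country draws one factor per category,
`exp(σZ − σ²/2)` with `σ² = ln(1 + CV²)`, so expectations equal the
archetype means and intakes stay positive. The factor is shared across
a country's strata, keeping gender strata coherent. Everything is
driven by one `numpy` Generator seed: identical seed and specs give
bitwise-identical tables.

What passing pipeline tests show — and what they do not: at zero noise
the five analyses recover the generating archetypes exactly (agreement
1), and average recovery over 20 seeds decays monotonically as CV grows
(≈0.88 at the default 0.15, ≈0.23 at 0.8 in the packaged conditions
with three countries per archetype). This validates the mapping →
scoring → clustering chain end to end, but says nothing about whether
real European countries cluster this way: real data have correlated
categories, survey-methodology artifacts and far less clean regional
structure. The frozen printed fixtures (per-country totals and the
four-region map) cover the normalization/summary arithmetic on real
published numbers; the per-category inputs behind them are not public
in the main text, so component-level country results are exercised only
on synthetic data.

## Problem sizes and determinism

Test and example analyses use 8–12 countries (×3 strata), matching the
intended scale of the method; acceptance-style pipeline checks run 20
seeds × 4 noise levels in a few seconds. Every stochastic step takes an
explicit seed, all tie-breaks are deterministic, and pipeline outputs
embed a configuration hash and the package version so artifacts are
traceable to their inputs.

## Known limitations

- Population means hide within-population variability; strict
  components degenerate to 0/10 at this granularity (see above).
- The packaged EAT-Lancet bands and sugar coefficients are defaults,
  not published values; substantive analyses should supply their own.
- No inferential statistics are provided (none are defined for this
  design); summaries are descriptive.
- The generalized Ward objective on raw vs squared Gower
  dissimilarities is a genuine methodological fork; raw is the default
  here, and squared-input behaviour can be obtained by squaring the
  matrix before agglomeration.
- No bootstrap or stability analysis of clusters; silhouette widths are
  the only partition diagnostic.
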