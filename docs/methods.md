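# Methods

This note documents the models, conventions and numerical choices behind
`mycograze`, and what the synthetic-survey tests do and do not establish about
real field data.

## Survey data model

Sampling units are keyed `forest/treatment/quadrat/subquadrat`. The default
design is three forest types × two treatments (grazed/ungrazed), three 400 m²
quadrats per plot, four 100 m² subquadrats per quadrat, giving 12
subquadrat-level units per plot type (72 in total) and 3 quadrat-level units
per plot type (18 in total). Analyses accept either level; quadrat-level
aggregation sums individual numbers and ORs presence across the four
subquadrats.

Observations are tidy long records (unit, species, individual_number ≥ 1);
absent species are implicit zeros, which suits sparse field data better than a
wide species × unit matrix (a `wide_to_long` converter is provided). Trait
labels are normalized case- and plural-insensitively onto fixed enumerations
("Wood saprotrophs" → "wood saprotroph", "Agaricoid fungi" → "agaricoid"), so
field spreadsheets with inconsistent capitalization validate cleanly; an
unknown label is an error naming the offending value.

## Individual-number coding

A species' sporocarps within one unit are grouped by single-linkage clustering
cut at 2 m: pairs chained by steps ≤ 2 m belong to one group, anything farther
is a separate individual. Within a group, the *adjacency gap* is defined as
the largest edge of the group's minimum spanning tree — the smallest step size
at which the group is connected. This is the natural single-linkage reading of
"adjacent sporocarps inside this group", and on collinear chains it equals the
largest gap between consecutive sporocarps. The gap maps to the code via
inclusive bounds: singleton → 1, ≤ 0.5 m → 2, ≤ 1 m → 3, ≤ 2 m → 4.

Two conventions are genuinely open and were fixed as follows:

- A unit's individual number for a species is the **sum** of its group codes
  (`combine="sum"`); taking only the largest group's code is available as
  `combine="max"`.
- Points are assigned to the subquadrat containing them; there is no
  cross-unit clustering, since subquadrats are the minimum recording units.

Correctness is checked against an independent union-find/Kruskal oracle on
random point sets and on planted configurations with known codes.

## Diversity indices

Simpson (1 − Σpᵢ²), Pielou (H/ln S) and Margalef ((S−1)/ln N) use natural
logarithms throughout. Two degenerate cases need conventions:

- **Eve at S ≤ 1** is undefined (ln 1 = 0) and returned as NaN, never 0 or 1;
  report tables render it blank.
- **Ric at N = 1** (which forces S = 1) is defined as 0, the S = 1 limit.
- Units with no sporocarps at all get Div = Ric = 0 and undefined Eve in the
  per-unit table, so empty units still enter the treatment contrasts.

The implementations are cross-checked to 1e−12 against scikit-bio's
`simpson`, `pielou_e` and `margalef` on random abundance vectors.

## Treatment contrasts

`mann_whitney` delegates to `scipy.stats.mannwhitneyu`: the exact permutation
distribution when the pooled sample is tie-free and has ≤ 25 values, otherwise
the normal approximation with midranks, tie correction and a 0.5 continuity
correction. U₁ counts (ungrazed > grazed) pairs with half-credit ties;
U₁ + U₂ = n₁n₂ exactly.

Cliff's delta is evaluated exactly as a rational number from the reported
U = min(U₁, U₂), which makes every reported delta ≤ 0; direction is carried
separately by the conclusion code. Direction comes from the sign of the median
difference, falling back to the mean-rank difference on an exact median tie;
"no change" requires both to be zero. Magnitude bands |δ| < 0.147 / 0.33 /
0.474 separate negligible/minor/moderate/large effects.

Rendering: medians and deltas to 3 decimals with exact halves rounded away
from zero (−0.8125 → −0.813); when the third decimal is an exact half the
4-decimal form is preserved (−0.6875). Ranking and significance always use
unrounded values.

The nested design means subquadrats are not fully independent; the
nonparametric test is the analysis's stated remedy, and no mixed-effects
model is attempted.

## Dominance index

Dom_j averages a group's occupancy share and abundance share, in percent.
Group occupancy q_j is **additive** over member species (Σ member qᵢ) rather
than "units where any member occurs": only the additive reading makes complete
partitions sum to exactly 100% (and binary partitions exactly complementary),
which is how published attachment-type tables behave. The literal reading is
available via `occupancy="literal"` (it requires per-unit presence sets and
does not preserve the 100% identity). Ties in ranked tables share a rank,
extend a top-k table past k, and are flagged; display order among ties is
alphabetical.

## Ordination

The feature matrix joins Div/Eve/Ric with Lay-1/2/3 (cm), their sum Lays and
the ordinal remains level Rem (treated as numeric). Because the variables mix
units, PCA standardizes columns to zero mean and unit variance (correlation
PCA) and decomposes via SVD. Zero-variance columns (e.g. a decomposed layer
that is identically 0 in plantations) must be dropped first and are recorded
in an exclusion report. Lays is kept alongside its three summands; the
resulting exact collinearity simply yields a trailing zero eigenvalue and is
deliberate, as all four variables are of interest.

Conventions: undefined Eve is imputed as 0 with a warning (units with S ≤ 1
carry minimal evenness information; `eve_policy="drop"` removes them instead);
component signs are fixed so each loading vector's largest-magnitude entry is
positive, making results bit-for-bit reproducible; all min(n−1, p) components
are retained so explained fractions sum to 1 and scores × loadingsᵀ
reconstructs the standardized matrix. Pairwise Pearson correlations with
two-sided p-values back the PCA reading with sign/strength labels at α = 0.05.

## Spore-measurement notation

`summarize` reports `{a/b/c} (d) e–f (g) [h ± i, j]`. The ≥ 90% interval is
realized as a trimmed range: the default `symmetric` mode trims an equal count
from both tails and snaps the bounds outward to the recording grid (0.5 µm by
default); the `optimal` mode returns the minimal-width grid-aligned interval
that still covers, with ties broken toward symmetry. No quantile definition is
canonical for this notation, so coverage ≥ 90% is the guaranteed invariant
and minimality is guaranteed only in `optimal` mode. Extremes d/g are
reported at grid resolution and printed only when outside [e, f]. The mean
and sample SD (n−1 denominator) print at 2 decimals; the mode is the most
frequent grid value, smallest on ties. Shape ratios (Q = length/width per
spore) are computed before summarizing, rounded to 2 decimals, and never
grid-snapped. `parse_notation` inverts `format_notation` exactly at rendering
precision.

## Synthetic-survey generator

The generator emulates the survey's statistical structure; its defaults are
the study conditions, not tuning knobs:

- **Species pools**: 17 shared / 53 unique-grazed / 16 unique-ungrazed
  (86 total; 70 vs 33 per treatment), realized exactly — any pool species the
  occupancy model misses is planted once.
- **Abundance**: a geometric series per stratum with concentration θ;
  θ = 0.8 ungrazed (monopolistic dominance) vs θ = 0.3 grazed (balanced).
  A log-series would be the natural alternative; one parameter sweeping the
  monopolistic↔balanced axis was preferred.
- **Occupancy**: per-unit presence probability 1 − (1 − π)^A with base rate
  π = 0.35 and A the species' expected stratum abundance (total 60 per
  stratum), linking qᵢ to nᵢ as the dominance index assumes.
- **Individual numbers**: codes 1–4 sampled with abundance-weighted
  probabilities (1 + Binomial(3, min(0.85, 2w))), used when coordinates are
  not simulated; `generate_points` plants true coordinate clusters instead.
- **Traits**: sampled from treatment-dependent frequency tables — alga
  symbionts dominate the pre-grazing pool, wood/soil saprotrophs the species
  introduced under grazing; the pre-grazing pool is restricted to
  cosmopolitan/pantropical geographic components; the taxonomic order follows
  deterministically from the sporocarp type.
- **Environment**: gamma-distributed layer thicknesses on a 0.25 cm recording
  grid with forest-specific means (2.5/1.25/0.5 cm in secondary mixed forest,
  1.0/0.5/0 cm in plantations — the zero decomposed layer exercises the PCA
  exclusion path), multiplied by 0.5 under grazing; remains levels are
  rounded clipped normals shifted +1 level under grazing.

`SimulationConfig.null()` switches every treatment effect off (symmetric
pools, equal θ, no litter/remains shift) for false-positive calibration.

**What passing tests show — and do not.** Effect recovery (≥ 90% of seeds
flag richness ↑*, litterfall ↓*, remains ↑* in the pooled stratum) and null
calibration (per-variable false-positive rate ≤ 0.07 over 500 seeds) validate
the pipeline's wiring and the test's level under the generator's assumptions:
independent units, geometric abundances, clean treatment randomization. Real
surveys add spatial autocorrelation between subquadrats, detection failure in
dense vegetation, observer effects and taxonomic ambiguity, none of which the
generator emulates — so these tests certify the statistical machinery, not
field-inference validity.

## Problem sizes and determinism

Simulation-based checks use 100 seeds for effect recovery, 500 for null
calibration, 1000 random strata/sample pairs for the partition and oracle
invariants, and 200 planted point sets — sizes at which the binomial noise on
the checked rates is well below the asserted margins. All randomness flows
through `numpy.random.default_rng` seeded explicitly; two runs on the same
inputs produce byte-identical outputs (the report bundle exposes a SHA-256
digest over its rendered numbers to assert this).

## Known limitations

- The nesting of subquadrats within quadrats is acknowledged but not modeled;
  contrasts treat units as exchangeable, as the nonparametric test assumes.
- The dominance index has no sampling theory here; no test accompanies
  dominance differences.
- Rem is ordinal but enters PCA and correlations as numeric.
- The exact Mann–Whitney path is limited to tie-free pooled samples of ≤ 25;
  heavily tied ordinal variables always use the corrected normal
  approximation.
- The notation parser accepts only the canonical rendering (single en-dash or
  hyphen, `±` or `+/-`), not free-form ranges from the older literature.
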