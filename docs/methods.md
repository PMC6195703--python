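# Methods

This note documents the models, rules, and numerical choices behind
`fticrdom`, and what the synthetic benchmark does and does not demonstrate.

## Mass arithmetic and the element table

Monoisotopic element masses (C, H, O, N, P, S), isotope mass shifts, and
the electron mass are shipped as a plain-text table
(`src/fticrdom/data/elements.tsv`, ≥ 9 decimal places) so the numerical
basis of every assignment is diffable. The natural ¹³C/¹²C abundance ratio
defaults to 0.0107.

The ten chemical building blocks (CH₄−O, C₂H₂, C₂H₄, CH₂, H₂, H₂O, O,
CO₂, NH, S) carry masses recomputed from the element table at full
precision. Two of the conventionally quoted 6-decimal block values (CO₂,
CH₄−O) are themselves sums of 6-decimal-rounded element masses and differ
from the full-precision sums by one unit in the sixth decimal; we keep the
full-precision values and compare quoted values with ±1 ulp slack.

## Formula validity

A CHONPS composition is valid iff all of: C > 0; H > 0; N, O ≥ 0;
0 ≤ P ≤ 1; 0 ≤ S ≤ 1; C/3 ≤ H ≤ 2C + N + P + 2; N + H + P even; N ≤ C;
P ≤ O + S ≤ C + 2N + 3P. These are heuristic valence/parity constraints
appropriate for natural organic matter; they exclude most radical and
chemically implausible compositions but are not a guarantee of chemical
existence. Enumeration additionally restricts counts to
C₁₋₁₀₀H₁₋₁₅₀O₀₋₅₀N₀₋₄P₀₋₁S₀₋₁.

## Ion convention

All ions are singly deprotonated molecules, the universal convention for
negative-ESI DOM: M = m/z + m(H) − m(e⁻). No other adducts, charge
states, or polarities are modelled.

## Clustering into operational units

Peaks from all samples are pooled, sorted by m/z, and chained by single
linkage: a unit boundary is drawn wherever the gap to the previous peak is
≥ 1×10⁻⁶ × (previous m/z); membership therefore requires a relative gap
strictly below the tolerance. The tolerance is applied pairwise between
adjacent peaks, not to the cluster centroid — a deterministic O(n log n)
rule whose transitive closure equals an all-pairs union-find at the same
pairwise criterion (pinned by a brute-force oracle in the tests). A
consequence is that a dense ladder of sub-tolerance gaps can chain into a
wide unit; the member m/z spread is available per unit for QC. Two peaks
from the same sample that land in one unit have their intensities summed
(possible under-resolution). The representative m/z is the
intensity-weighted mean of members, which always lies inside the member
range.

Filtering: singleton units are dropped; units with fewer than 10 member
peaks are excluded from annotation; an optional occupancy filter keeps
units present in ≥ k distinct samples.

## Formula assignment

1. **Enumeration.** For a unit's neutral mass, all valid formulas within
   the assignment tolerance (default 1 ppm; the clustering tolerance and
   the assignment tolerance are configured independently) are enumerated
   by looping over S, P, N, O, bracketing C from the residual mass and
   solving H from the remainder — exactly equivalent to scanning the full
   element grid, at a small fraction of the cost.
2. **Carbon-number estimate.** The unit at +1.003355 Da (within relative
   tolerance) is taken as the ¹³C satellite; C_est = (I_iso/I_mono)/0.0107
   with intensities summed over the samples shared by the two units
   (default) or as the median of per-sample ratios (option; more robust
   when one sample's satellite is contaminated).
3. **Selection.** C_dev = C_candidate − C_est. Candidates with C_dev
   outside the open interval (−3, 1) are discarded; among survivors the
   smallest |C_dev| wins, with ties broken by smaller |mass error| and
   then lexicographic formula order. "Smallest C_dev" is deliberately read
   as smallest *absolute* deviation: a signed reading would prefer a
   candidate at −2.9 over one at −0.1, defeating the point of the
   verification. The interval is open at both ends, following the
   parenthesis notation.
4. **Building-block propagation.** Verified formulas act as scaffolds;
   an unassigned unit whose representative m/z sits one signed block mass
   from a scaffold (within relative tolerance) inherits the block-shifted
   formula, provided the result is valid, inside the element bounds, and
   within the assignment ppm tolerance of the unit's own neutral mass.
   Propagation is breadth-first for at most `max_hops` rounds (default 3 —
   unbounded chaining compounds errors); each round only consumes
   scaffolds existing when the round started, and conflicts are resolved
   by smallest |mass error|, then scaffold majority vote, then
   lexicographic formula, so the outcome is independent of processing
   order. Block-annotated units carry `route="building_block"` so users
   can stratify confidence.
5. **Isotopologue labelling.** For each annotated unit, units at the ten
   isotopologue shifts are linked when the parent formula contains the
   substituted elements (³⁴S needs S ≥ 1, ¹³C₃ needs C ≥ 3, …) and the
   partner does not itself carry a formula annotation. Linked satellites
   are excluded from the molecule inventory.

Whether the original in-house implementations of this workflow aggregated
isotope intensities per sample or across clusters is generally not
documented; both modes are provided (`aggregation="sum" | "median"`).
The assignment ppm tolerance is likewise surfaced in the QC report rather
than hidden, since published workflows rarely state it.

## Compound classification

The six stoichiometric classes overlap as usually printed (H/C = 2.0
satisfies both the carbohydrate rule and the aliphatic window), so
assignment is an ordered cascade, saturated/carbohydrate rule first:

1. H/C ≥ 2.0 or O/C ≥ 0.9 → saturated/fatty/carbohydrate-like
2. AI > 0.66 → polycyclic aromatic
3. 0.50 < AI ≤ 0.66 → polyphenol
4. AI ≤ 0.50 and H/C ≤ 1.5 → phenolic/highly unsaturated
5. AI ≤ 0.50, 1.5 ≤ H/C < 2.0, N = 0 → unsaturated aliphatic
6. AI ≤ 0.50, 1.5 ≤ H/C < 2.0, N ≥ 1 → peptide-like (N-containing)

The cascade is total: every valid formula receives exactly one class. At
shared edges (AI exactly 0.50 or 0.66, H/C exactly 1.5 or 2.0,
O/C exactly 0.9) the conventions above are explicit and test-pinned, but
whether any given legacy implementation used open or closed boundaries is
unknowable from published descriptions — only the convention is
guaranteed, not cross-software agreement on boundary formulas. The
aromaticity index defaults to the standard form; the modified variant
(O → O/2) is available behind a flag. Non-positive numerator or
denominator clamps AI to 0.

## Weighted van Krevelen density

The density on the (O/C, H/C) plane is a weight-normalised sum of
axis-aligned bivariate normal kernels. Weights for a sample group are the
per-unit medians of sum-normalised intensities (zeros included by
default). Per-axis bandwidths follow the bivariate normal-reference rule
h_j = σ_j · n_eff^(−1/6) on the weighted sample, with effective sample
size n_eff = (Σw)²/Σw² (for d = 2 the Scott constant (4/(d+2))^(1/(d+4))
is exactly 1). The default grid is 200×200 spanning the data range padded
by 3 bandwidths per side, over which the trapezoidal integral of the
density is 1 to within ~10⁻³ (only extreme-edge points lose one-sided
tail mass). All points coinciding on an axis is a degenerate-bandwidth
error with guidance to pass an explicit bandwidth.

## Ecology statistics

- Intensities are converted to pseudo-counts for rarefaction by
  sum-normalising, scaling to a pseudo-depth (default 43,000), and
  rounding half-to-even; the exact rounding rule used by legacy pipelines
  is generally unstated, so ours is documented here. Rarefaction draws
  without replacement (multivariate hypergeometric) to exact depth;
  defaults of depth 9,000 × 10 repetitions mirror common practice for DOM
  molecule tables.
- Chao1 uses F₁²/(2F₂) with the bias-corrected form when F₂ = 0; Shannon
  defaults to log base 2 (the QIIME 1 convention), natural log optional.
- Bray-Curtis comes from `scipy.spatial.distance`; Mantel and PERMANOVA
  are implemented here because the permutation contract (seeded
  generator, one-sided p = (#{stat ≥ observed} + 1)/(n_perm + 1), never
  zero) is part of the interface; scikit-bio's implementations serve as
  independent cross-checks in the test suite. Mantel defaults to Pearson
  correlation of the lower triangles (the vegan default), Spearman
  optional. PERMANOVA is Anderson's pseudo-F with R² = SS_between/SS_total.
- All stochastic operations take a seed and are bit-reproducible.

## Synthetic benchmark

The generator renders each formula as its [M−H]⁻ monoisotopic peak plus a
¹³C satellite at intensity ratio C × 0.0107 — the linear single-substitution
model that mirrors the estimation formula, not the full binomial
isotope distribution (a lognormal perturbation of the ratio is available
for stress tests) — and a ³⁴S satellite at ratio 0.0447 when sulfur is
present. Degradations: multiplicative lognormal intensity noise
(σ = 0.8), Gaussian ppm mass jitter (σ = 0.5 ppm), uniform-m/z noise
peaks (0.2 per Da) whose S/N straddles the 5 threshold, and five
blank-contaminant formulas spiked into every sample and rendered into two
blank spectra. The standard benchmark is 100 formulas over 150–700 Da in
a DOM-like category mix, two groups of six samples, with a 2× peptide
multiplier in group A as a recoverable group effect. Per-peak provenance
is recorded, so recovery is scored exactly: a truth formula is
*recoverable* when some post-filter unit consists (by majority) of that
formula's monoisotopic peaks, and *recovered* when that unit was
annotated with exactly that formula.

What passing these tests shows: the assignment logic, tie-breaks, and
statistics are internally correct and calibrated under realistic noise
magnitudes. What it does not show: robustness to instrument artefacts the
generator omits — resolution-limited peak shapes, space-charge m/z
shifts, adduct chemistry, isotope patterns beyond the linear model — or
performance on real spectra with far denser peak populations per nominal
mass.

## Problem sizes and numerical tolerances

Enumeration is audited against a vectorised full-grid oracle for 200
random masses ≤ 500 Da at 1 and 5 ppm. Permutation-test calibration uses
20-sample null datasets, 99 permutations, and 500 replicates, asserting
the empirical type-I error at nominal 0.05 within 3σ Monte-Carlo slack.
The KDE is compared to a direct kernel-sum at 10⁻¹⁰ absolute. Relative
m/z comparisons use the tolerance × target-m/z convention throughout;
composite isotopologue shifts are exact sums of their components (checked
at 10⁻⁹ Da).
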