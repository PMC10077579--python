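# Methods

## Scope and data model

`domdiv` analyzes calibrated negative-ion FT-ICR MS peak lists, one per
sample, together with a per-sample metadata table (lake type, coordinates,
EC, pH, temperature, DIN, optionally DOC and optical indices). All ions are
treated as singly charged, even-electron deprotonated molecules [M−H]⁻;
adducts, multiply charged ions, isotope-pattern scoring and spectral
processing upstream of the peak list (peak picking, recalibration) are out
of scope. Molecular formulas are element-count tuples over C, H, N, O, S,
P; isomers are unresolved, so every diversity measure is a conservative
lower bound on true molecular diversity.

## Formula assignment

The neutral mass of a peak is m/z + 1.00727646 Da. Candidates are
enumerated exhaustively over configurable element ranges (defaults
C 1–60, H 1–122, O 0–40, N 0–4, S 0–2, P 0–1) within a relative tolerance
(default 0.5 ppm), by solving the hydrogen count from the mass residual on
a vectorised C × O grid inside explicit N, S, P loops — exhaustive and
deterministic. Chemical filters then require an integer DBE ≥ 0 (even-
electron neutral molecule), 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1, and O ≥ 4P. The
phosphate rule exists because P in natural organic matter occurs as
phosphate esters, and because the 4N + 6O ↔ 10C + H + P substitution
(Δ = 0.197 mDa) otherwise produces spurious P-bearing matches for O-rich,
N-rich formulas above ~300 Da.

Remaining ties are broken by (1) fewest P, (2) fewest N + S, (3) smallest
|mass error|, (4) canonical form. P is ranked before the other heteroatoms
for the same reason the phosphate rule exists: a P assignment that is not
corroborated (e.g. by isotope fine structure, unavailable from a peak
list) is far less probable a priori than an N- or S-bearing alternative.
With these rules, round-tripping random valid formulas (150–500 Da,
±0.2 ppm perturbation) through assignment recovers ≥ 99%; the measured
ambiguity rate (more than one surviving candidate) is reported by the
test. Ambiguity grows with mass — above ~500 Da occasional
S ↔ CHNO near-isobars survive every filter, which is a physical limit of
0.5 ppm exact-mass assignment, not an implementation artifact.

## Molecular indices

For a formula with counts C, H, N, O, S, P:

* DBE = 1 + C − H/2 + (N + P)/2
* DBE_AI = 1 + C − O/2 − S − (N + P + H)/2 (the DBE of the molecular core
  after discounting heteroatom-attributable unsaturation; every term is a
  half-integer, so DBE_AI falls exactly on a 0.5 grid)
* AI_mod = DBE_AI / (C − O/2 − N − S − P), clamped to 0 when the numerator
  or denominator is non-positive; values > 1 are possible for condensed
  cores and are not clipped
* NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C

Compound categories are evaluated in the order saturated (DBE = 0), then
aromatic (AI_mod > 0.5), then unsaturated (H/C ≥ 1.5) versus highly
unsaturated (H/C < 1.5). The explicit precedence makes the four classes a
partition; without it the aromatic and unsaturated conditions can overlap.
The oxygen class splits at O/C ≥ 0.5.

I_Deg is the summed intensity of five degradation-associated reference
formulas divided by the summed intensity of all ten reference formulas
(five degradation- plus five freshness-associated CHO formulas of Flerus
et al. 2012, shipped as editable package data). When no reference formula
is detected the index is undefined and reported as NaN with a warning.

## Diversity

Relative abundances p_i are peak intensities normalized to the sample sum;
all assigned formulas enter D_A and D_F (no detection-limit subset is
applied beyond the optional blank filter).
D_A = 1 − Σ p_i² is the probability that two randomly drawn molecules are
different formulas. D_F(x) = Σ_ij p_i p_j |x_i − x_j| (Rao quadratic
entropy with the L1 property distance) is computed in O(n log n) via
sorting and cumulative sums; the naive double sum is retained as a test
oracle. Default properties: C count, H/C, N/C, AI_mod, DBE, NOSC, each
reported separately.

The Jensen–Shannon divergence uses base-2 logarithms, making it symmetric
and bounded in [0, 1], and is applied to presence-based histograms of
DBE_AI: each distinct formula contributes 1/D_R to its bin, intensities
deliberately unused. An intensity-weighted variant exists but is off by
default. Histograms are aligned on the union of the two supports;
probability-0 bins contribute nothing (0·log 0 = 0), which keeps the
divergence well defined for disjoint supports (where it attains exactly
1). Bray–Curtis dissimilarity of the normalized sample × formula matrix is
provided for comparability with intensity-based studies and is the input
to the Mantel tests.

## Community analysis

Clustering is average-linkage agglomerative on a distance matrix; the
dendrogram is cut at each k in 2..min(10, n−1) and the k maximizing the
mean silhouette width — computed against the original distances, not
ordination coordinates — is selected, ties going to the smallest k with a
warning. NMDS is rank-based (Kruskal stress-1, normalized), best of
several random starts, seeded. Environmental vectors are fitted post hoc
by least squares on the ordination axes; r² = 1 − SS_res/SS_tot and the
p-value comes from permuting the variable across samples.

IndVal follows the original Dufrêne–Legendre form: specificity
A_ic = mean abundance of formula i in cluster c divided by the sum of its
cluster means (group-size unweighted), fidelity B_ic = occurrence fraction
within the cluster, IndVal_i = max_c A_ic·B_ic. Abundance is the
normalized intensity, as "relative average abundance" implies. The
permutation test permutes cluster labels with the max-over-clusters
statistic; p-values are Benjamini–Hochberg adjusted across formulas with
significance at adjusted p ≤ 0.05. With very small groups the attainable
p-value is floored by label-permutation collisions (e.g. 4-sample clusters
in a 16-sample survey give p ≥ ~0.003), which BH may leave above the
threshold; surveys with ≥ 5 samples per cluster avoid the floor.

Mantel tests correlate the lower triangles of two distance matrices
(Pearson, after standardizing each) with a one-sided (greater)
joint row/column permutation test, matching the directional hypothesis
that dissimilarities increase together. Spatial distance is the great
circle on a sphere of radius 6371.0088 km. Environmental distance is
Euclidean on z-scored variables (sample standard deviation, ddof = 1); EC
is log10-transformed before z-scoring by default because it spans about
four orders of magnitude across lake types. All permutation p-values use
(1 + exceedances)/(n_perm + 1) and every randomized routine takes an
explicit seed.

## Synthetic surveys

The generator is phenomenological: mechanisms act as inclusion-probability
modifiers, not kinetics. A shared pool of three source classes is drawn by
rejection sampling within the assignment module's own chemical filters —
"fresh" high-H/C N-bearing formulas (H/C ≥ 1.5, N 1–4), humic-like
aromatics (AI_mod > 0.5), and highly unsaturated backbones — so every
generated peak list survives formula assignment. Per lake, the inclusion
probability of a pool formula is

```
p = base_rate × type_weight(class, lake_type) × exp(−strength · x · w)
```

where x = max(0, log10 EC − (−2.5)) is a salinity score anchored at the
dilute end of the survey, and w = clip(AI_mod, 0, 1) is the formula's
aromaticity weight. Anchoring x at the dilute end (rather than z-scoring
around the survey mean) keeps degradation a pure removal process; a
mean-centered score would imply probability boosts above 1 for dilute
lakes. High pH additionally penalizes oxygen-rich aromatics. Hypersaline
lakes convert a fraction (default 0.3) of retained formulas to an
S-bearing analog (one O swapped for one S, preserving the H and DBE
grids); proglacial lakes up-weight N-bearing formulas. The per-class type
weights form a staircase (proglacial > freshwater > saline > hypersaline
in total weight) so that molecular richness declines monotonically along
the EC gradient, as observed in real lake surveys.

Each lake type additionally carries a small accessory subpool (default 100
formulas at 95% inclusion in its own type, 4% elsewhere, and never for the
sulfurized hypersaline accessories, which require sulfide) whose element
ratios place it in a characteristic DBE_AI band: proglacial polyol-like
aliphatics (DBE_AI ≈ −12…−6), freshwater terrestrial polyaromatics
(≈ 12…19), saline large refractory backbones (mid-range), hypersaline
sulfurized condensed aromatics (≈ 21…30). These bands are what give each
lake type a distinct DBE_AI histogram signature over and above the class
mixture — without them, between-type Jensen–Shannon divergences sit at
the histogram sampling-noise floor (≈ number of bins / 4·D_R) and
clustering cannot resolve four groups. Fifteen further marker formulas per
type are planted deterministically (present in every lake of the type,
absent elsewhere); they are the exact ground truth for indicator-formula
recovery. Intensities are lognormal (ln-scale mean 16, sd 1); observed m/z
is the [M−H]⁻ mass with Gaussian ppm jitter (sd 0.2 ppm, truncated at 2σ,
representing post-calibration QC); peaks colliding within 0.2 mDa keep the
more intense member. Coordinates are drawn uniformly in an Antarctic
coastal box independently of all environmental variables, so composition
tracks the environment but not space by construction.

Environmental regimes per lake type (log10 EC in S m⁻¹: −2.2, −1.3, 0.3,
1.3 with sds 0.2–0.35; pH 7.3→8.5; DIN elevated in hypersaline lakes; DOC
increasing with EC) were chosen once to mirror the ranges reported for
Antarctic coastal lakes.

What the generator does *not* emulate: isotopologues, adducts,
intensity-dependent detection limits, correlated replicate noise, real
spatial autocorrelation of chemistry, or NMR/optical observables. Tests
passing on synthetic surveys therefore demonstrate that the pipeline
recovers structure of this idealized kind; they do not validate
instrument-level behavior on field data.

## Numerical choices and limitations

* Duplicate m/z within 0.1 mDa are rejected at ingest; intensities must be
  positive; the default mass window is 92–1000 Da (lower bound from the
  typical scan range; DOM signals concentrate below 1000 Da).
* Blank filtering retains a sample peak matched to a blank peak within
  0.5 ppm only if it is ≥ 5× the blank intensity (both configurable);
  replicate QC flags Bray–Curtis > 0.05 between re-runs of a reference
  sample.
* The sample × formula matrix orders columns by exact mass (ties by
  element counts) for bit-stable output; row normalization is idempotent
  and errors on zero rows.
* Silhouette-based k selection can legitimately return "no valid k" for
  degenerate (all-equal) distances; the smallest k is then returned with a
  warning.
* Problem sizes in the test suite (e.g. 800 formulas for the assignment
  round-trip, 500 replicates × 999 permutations for null calibration, a
  40-lake default survey) are the package's chosen reference scales:
  large enough that binomial noise is well inside the asserted margins.
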