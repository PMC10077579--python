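# domdiv — molecular diversity of dissolved organic matter from FT-ICR MS

Dissolved organic matter (DOM) is a mixture of tens of thousands of
compounds. Ultrahigh-resolution mass spectrometry (FT-ICR MS) resolves it
into molecular formulas, which can then be treated the way ecologists treat
species: each formula is a taxon, its normalized peak intensity a relative
abundance. `domdiv` implements that analysis end to end for surveys of
lakes (or any set of water samples) measured as calibrated negative-mode
peak lists:

* **Formula assignment** — exhaustive CHNOSP search over the neutralized
  [M−H]⁻ mass at sub-ppm tolerance, with chemical-plausibility filters
  (integer DBE ≥ 0, H/C and O/C bounds, O ≥ 4P) and a deterministic
  heteroatom-parsimony tie-break.
* **Molecular indices** — DBE, DBE_AI, the modified aromaticity index
  AI_mod = DBE_AI / (C − O/2 − N − S − P), NOSC, elemental ratios, the four
  compound categories (aromatic / highly unsaturated / unsaturated /
  saturated, each split at O/C = 0.5), and the degradation index I_Deg.
* **Alpha-diversity** — richness D_R; Gini-Simpson D_A = 1 − Σ pᵢ²; Rao
  functional diversity D_F(x) = Σᵢⱼ pᵢ pⱼ |xᵢ − xⱼ| for chemical
  properties x (C count, H/C, N/C, AI_mod, DBE, NOSC).
* **Beta-diversity** — Jensen–Shannon divergence (base-2 logs, bounded in
  [0, 1]) between presence-based histograms of DBE_AI on its natural 0.5
  grid, and Bray–Curtis dissimilarity of normalized intensities.
* **Community analysis** — average-linkage clustering with
  silhouette-chosen k, non-metric multidimensional scaling, post-hoc
  environmental vector fitting, indicator-formula analysis (IndVal) with
  permutation tests and Benjamini–Hochberg adjustment, and Mantel tests of
  composition against great-circle distance and z-scored environmental
  distance.
* **Synthetic surveys** — a generator producing peak lists plus metadata
  for lakes spanning a proglacial → hypersaline salinity gradient, with
  photodegradation, sulfurization and N-enrichment mechanisms and known
  ground truth, so the whole pipeline is testable without field data.

## Worked example

`examples/` contains one short script per capability. For instance,
clustering a 16-lake synthetic survey on the Jensen–Shannon divergence of
binned DBE_AI distributions (`examples/05_beta_diversity_clustering.py`)
prints:

```
optimal k = 4, mean silhouette = 0.712
cluster      1  2  3  4
lake_type
freshwater   4  0  0  0
hypersaline  0  4  0  0
proglacial   0  0  4  0
saline       0  0  0  4

NMDS stress = 0.0045
```

The silhouette-optimal cut recovers the four lake types exactly, and the
near-zero stress says the dissimilarity structure embeds faithfully in two
dimensions. The distance-decay script (`examples/07_distance_decay.py`)
prints

```
composition vs environment: r_M = +0.617, p = 0.0010
composition vs space:       r_M = +0.211, p = 0.0650
```

— compositional turnover follows the environmental gradient, not
geography, which is exactly how the survey was constructed (coordinates
are drawn independently of lake chemistry).

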