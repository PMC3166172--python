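# poolscreen

Analysis pipeline for pooled fitness screens of the yeast deletion
collection on barcode (TAG) microarrays, of the kind used to find the genes
a cell needs to tolerate a toxicant. The motivating design: pools of ~4,600
homozygous deletion strains grown for 5 or 15 generations in three
sub-inhibitory doses of a compound (25%, 50% and 100% of the concentration
that inhibits wild-type growth by 20%, the IC20), three replicate chips per
treatment, compared against 12 rich-media control chips. Each strain is
quantified by two independent barcodes (UP and DOWN tags).

The package implements every analysis stage as a library, exercised
end-to-end on synthetic data with known planted truth:

* **`datagen`** — synthetic pools (log2-additive signal model with chip
  random effects, a fixed UP/DOWN tag offset, and planted dose-dependent
  depletion: a strain losing a fraction *d* of a doubling per generation is
  depleted by *d·g* log2 units after *g* generations), pathway graphs,
  scored interaction networks with planted modules, and logistic growth
  curves.
* **`normalize`** — faster cyclic loess ("fastlo"): each chip's deviation
  *M* from the across-chip mean profile *A* is smoothed (local linear
  regression, tricube weights) and subtracted, sweeping chips until the
  largest adjustment drops below tolerance. UP and DOWN barcodes are
  normalized as separate measurements, then averaged per strain.
* **`dssa`** — differential strain sensitivity analysis: the fitness score
  `mean(log2 treated) − mean(log2 control)` per strain and condition
  (negative = sensitive), Welch significance with Benjamini–Hochberg
  q-values (q < 0.05), and the ≥3-of-6-conditions consensus filter.
* **`dosemodel`** — gene-wise mixed models
  `Y = μ + chip(random) + δ·[DOWN] + β_dose + ε` fit by maximum likelihood
  (profiled chip-variance grid + GLS), likelihood-ratio test of the three
  dose effects against χ²₃, Holm step-down selection at 0.05; Kruskal–Wallis
  H across the 12/3/3/3 dose groups as the gene-level statistic for pathway
  testing.
* **`enrichment`** — hypergeometric category enrichment (p < 0.01),
  the ≥60% measured-coverage pathway filter, a graph-aware permutation
  pathway test (statistic: node mean plus mean of edge-wise minima, so
  perturbations that are neighbors in the pathway graph score higher than
  scattered ones), and clustering of −log10 p profiles (Spearman distance,
  average linkage, Newick export).
* **`network`** — sub-network detection around significant genes on a
  score-filtered (≥700) interaction network, with a degree-matched
  resampling null that respects hub bias, and per-cluster category
  annotation.
* **`growth`** — trapezoid AUC over 24 h of 15-minute OD readings, percent
  of control with delta-method standard errors, ICx by linear interpolation,
  and the 25/50/100% IC20 exposure ladder.

The package also ships transcriptions of the three printed per-compound
consensus tables (31 hydroquinone, 33 catechol and 12 benzenetriol genes)
used as parsing and consensus-filter fixtures.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on one
simulated screen and write tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_dssa.py
python analysis/04_dose_models.py
python analysis/05_pathway_enrichment.py
python analysis/06_network_clusters.py
python analysis/07_growth_curves.py
```

Output of the simulation and DSSA stages (4,607 strains, 40 planted
sensitive strains with dose-dependent defects of 0.15/0.25/0.4 of a
doubling per generation, i.e. −2 to −6 log2 depletion depending on dose
and generation):

```
pool: 9214 strain-tag rows x 42 chips; 40 planted sensitive strains
significant calls: 253 across 6 conditions
consensus genes (>=3 of 6): 40; planted recovered: 40/40; spurious: 0
```

All 40 planted strains pass the ≥3-of-6 consensus filter with no spurious
consensus genes; the dose-model stage Holm-selects the same 40 at both
generations (`40 Holm-selected genes; planted recovered 40/40; spurious
0`), the pathway stage ranks the planted pathway first in both generations
(`most enriched pathway pw000 (p=0.0001)`), and the network stage isolates
the planted module (`best: cluster01 (12 significant of 57 nodes,
p=0.0001)`). The growth stage reads the IC20 off the simulated wild-type
dose-response and prints the 25%/50%/100% exposure ladder:

```
dose  0.0 mM:  100.0% of control (SE 0.58, n=3)
dose  4.0 mM:   71.9% of control (SE 0.29, n=3)
dose  8.0 mM:   23.1% of control (SE 0.22, n=3)
IC20 = 3.01 mM -> exposure ladder: 25% = 0.75 mM, 50% = 1.50 mM, 100% = 3.01 mM
```

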