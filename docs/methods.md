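# Methods

## The measurement model

A pooled deletion-collection screen measures strain abundance by
hybridizing amplified strain barcodes to a TAG array. We work on the log2
scale throughout. The synthetic generator produces, for strain *s* with
tag *j* on chip *i*,

    Y_sij = a_s + Δ_s(dose_i, g_i) + b_i + δ·[j = DOWN] + ε_sij

with strain baselines `a_s ~ N(10, 1)` (log2 units), chip random effects
`b_i ~ N(0, σ_chip²)`, a fixed DOWN-tag offset δ, and residual noise
`ε ~ N(0, σ_noise²)`. A planted strain with growth defect *d* (fraction of
a doubling lost per generation, per dose) is depleted by

    Δ_s = −d · g        (log2 units after g generations)

because every doubling of the unaffected pool is one log2 unit of relative
abundance gained over a non-dividing strain. This makes the planted truth
analytically checkable: a defect of 0.4 at 5 generations is −2 log2, and
15-generation depletion is exactly three times 5-generation depletion.

Defaults mirror the study design the package models: 4,607 strains, 12
control chips versus 3 replicate chips at each of 3 doses (25%, 50%, 100%
of the wild-type IC20), generations 5 and 15, δ = 0.5, σ_chip = 0.2,
σ_noise = 0.3 (all log2). The variance defaults are our choice of a
realistic regime — chip effects somewhat smaller than residual tag noise —
since no signal-level variances are published for this design; the control
chips are generated per generation, with a switch (`share_controls`) for a
single control set, since the sharing structure across generations is not
documented. Signals are generated directly on the log2 scale; there is no
scanner-level intensity model, because every downstream analysis consumes
log2 signals only.

## Normalization (faster cyclic loess)

Classical cyclic loess normalizes all chip pairs; the faster variant fits
each chip once per sweep against the mean pseudo-chip: A = row-wise mean
across chips, M = chip − A, subtract the smoothed M-versus-A curve, repeat
until the largest adjustment is below `tol`. The smoother is local linear
regression with tricube weights (statsmodels lowess), span 0.4, two
robustness iterations, with the standard `delta` shortcut (fits evaluated
on a grid spanning 1% of the A range and interpolated). Span, robustness
count and `tol` (default 0.01 log2, `max_iter` 10) are configuration, not
claims about the original implementation, which published none of them.

Two properties anchor the tests: chips differing by constants are driven
onto the common mean within one sweep (the smooth fit of a constant M is
that constant), and the procedure is idempotent once converged. Formal
convergence below `tol` is not guaranteed. With few strains the smoother's
residual noise wiggle (roughly σ_noise/√(span·N) for N measurement rows)
can exceed `tol`; and when a visible fraction of strains is strongly
depleted on the treated chips (several log2 units, as at 15 generations),
those rows drag their own row means, cluster in one region of the A axis,
and keep re-creating local structure after every subtraction, leaving a
persistent adjustment plateau of a few hundredths of a log2. In both cases
sweeps stop at `max_iter`, the report says so, and the adjustment sequence
still decreases monotonically after the first sweep; downstream fitness
scores are insensitive to the residual (planted recovery on the full-scale
design is exact despite a ~0.016 plateau). UP and DOWN barcodes
are separate rows during normalization and are averaged per (strain, chip)
afterwards; a strain masked on both tags stays masked.

## Differential strain sensitivity (DSSA)

Fitness score per strain and condition: mean log2 signal over treated chips
minus mean over the condition's control chips; negative means the deletion
strain depleted, i.e. the gene is required for tolerance. Significance is a
variance-moderated unequal-variance t test on chip-level values with
Benjamini–Hochberg q-values within each condition (q < 0.05), and the
consensus filter flags genes significant in ≥3 of a compound's 6
conditions. The per-treatment test of the original screen lives in an
earlier methods paper and is not reproduced here; a calibratable
two-sample test is the stand-in.

Why moderation is not optional at this design: with 3 treated chips the
per-strain treated variance has 2 df. A plain Welch statistic then has a
far tail so heavy (its size at p ≈ 10⁻⁴ is inflated ~50-fold) that
Benjamini–Hochberg loses false-discovery control — null strains whose
variance estimate collapses produce minute p-values at fitness scores of
only ±0.3 log2, and a genuine −4 log2 hit occasionally lands above
q = 0.05. Each group's per-strain variance is therefore shrunk toward the
across-strain consensus before entering the statistic, exactly as in
standard small-replicate array practice: sample variances are modeled as
scaled-F draws around a prior (s₀², d₀) estimated by matching the moments
of log s², the posterior variance (d₀s₀² + d·s²)/(d₀ + d) replaces s², and
the prior df is added to each group's df in the Satterthwaite formula.
Plain Welch remains available (`moderated=False`) and its inflated size at
the screen design (≈ 0.075 at nominal 0.05) is asserted as a documented
band. The moderated test is calibrated to within binomial noise even at 3
versus 12 chips, and attains sensitivity ≥ 0.9 with false-discovery
proportion ≤ 0.1 for −2 log2 planted effects (noise 0.3) over 50 simulated
screens when the planted fraction matches the screen's observed hit rate
(~3.5% of strains). At markedly higher planted fractions the normalization
itself becomes a small bias source: the depleted strains drag the mean
pseudo-chip and the loess curve, shifting null scores upward by a few
hundredths of a log2 — a compositional effect worth remembering when many
strains respond.

The consensus filter counts significance of either sign by default because
the printed catechol consensus table contains a resistant (positive-score)
gene; a `negative_only` mode reproduces the sensitive-only framing.

## Gene-wise mixed dose models

For one compound and one generation (generations are always analyzed
independently), the tag-level model is

    Y_ij = μ + b_i + δ·[j = DOWN] + β_d·[dose(i) = d] + ε_ij,
    b_i ~ N(0, σ_chip²),  ε ~ N(0, σ_res²)

with μ the control-chip UP-barcode mean, categorical dose effects, and the
chip random intercept absorbing the UP/DOWN correlation within a chip. Fits
are maximum likelihood (not REML) so the full and dose-free reduced models
have comparable likelihoods; the dose effect is the LRT against χ² with one
df per dose level. ML is implemented by profiling λ = σ_chip²/σ_res² on a
fixed 61-point grid (0 plus a log grid from 10⁻³ to 10²): for fixed λ the
chip-block covariance inverts analytically, the fixed effects are GLS and
σ_res² has a closed profile form, so the whole fit is deterministic and
vectorizes across genes sharing a design. Logliks agree with R nlme ML fits
to < 0.02 on test genes. Masked measurements are dropped from the
likelihood (per-gene fallback path); σ_chip estimated at 0 is kept and the
LRT is still referred to χ²₃, a deliberate boundary simplification.

Two calibration facts shape the tests. First, chip random effects are
shared by all strains on a chip, so on *raw* signals the gene-level LRTs of
one pool are strongly correlated and the per-pool null rejection fraction
is wildly variable. The models are therefore fit — as in the real pipeline
— to fastlo-normalized signals, which removes the shared chip shifts and
restores near-independence across genes. Second, with 21 chips (42 tag
observations, 7 parameters) the ML LRT retains a small upward bias
(null rejection ≈ 0.058 at nominal 0.05), an intrinsic small-sample
property of the χ²₃ reference confirmed against nlme; Holm selection still
controls the family-wise error (measured ≈ 0.06 at nominal 0.05 over 500
simulated screens of 200 genes).

The Kruskal–Wallis H across the control/25/50/100 groups (12/3/3/3
replicates) is the gene-level statistic fed to pathway enrichment, computed
with tie correction; all-tied genes get H = 0. With these group sizes the
χ²₃ approximation to H's null distribution is itself only approximate
(CDF deviations of a few percent), so tests validate H against the exact
permutation reference rather than asserting uniform χ²-based p-values.

## Pathway and category enrichment

Category enrichment is the upper-tail hypergeometric p = P(X ≥ k) for a
k-gene overlap between a query and a K-gene category in an N-gene measured
universe (cutoff 0.01); it is checked against full enumeration for every
configuration with N ≤ 12. The population defaults to the union of
annotated genes and is overridable, since no population size is published.

The pathway test rewards topological proximity. For pathway graph (V, E)
and per-gene statistics s:

    T = (1/|V|) Σ_{g∈V} s_g + (1/|E|) Σ_{(g,h)∈E} min(s_g, s_h)

The edge term counts an edge only as high as its weaker endpoint, so high
statistics concentrated on adjacent genes raise T more than the same
values scattered. The null draws |V| statistics from the universe without
replacement, assigns them randomly to node positions and recomputes T;
p = (1 + #{T* ≥ T}) / (B + 1), ties counted as exceedances (conservative),
so p ≥ 1/(B+1) and never 0. The exact statistic of the published
structurally-enhanced enrichment method is defined in its own methods
paper; this node+edge form is our concrete proximity-rewarding variant and
is validated by its own properties — agreement with exhaustive assignment
enumeration on small universes, uniform null p-values, and
clustered-beats-scattered ordering — not by equivalence to the original.
Default 10⁵ permutations for production runs, 9,999 in tests. Pathways
need measured data for ≥ 60% of their genes (boundary inclusive) to enter.

Retained pathways' p-value profiles are −log10-transformed and clustered
with average linkage under Spearman distance 1 − ρ; rank-reversed profiles
sit at distance 2, constant profiles (undefined ρ) are placed at the
maximum distance with a warning, and missing p-values are imputed as 1
with a warning. The tree exports as Newick.

## Network modules

Interaction edges with confidence score ≥ 700 (inclusive) form an
undirected simple graph. Candidate sub-networks are connected components
of the subgraph induced by the significant genes plus their neighbors
within one hop; components with fewer than two significant nodes are
dropped. Because hubs make uniform-random nulls anti-conservative for any
cluster near them, cluster significance resamples the significant set
within log2-degree bins: each draw replaces every significant node by a
random same-bin node (without replacement per bin), and the p-value is the
plus-one fraction of draws placing at least as many resampled nodes in the
cluster as observed. Bins too small to supply their count are widened with
a warning. The original clustering methodology was unpublished; this
module is a transparent reconstruction honoring the stated hub-bias
concern, validated by planted-module recovery (a 12-node module in a
500-node preferential-attachment network is recovered at ≥ 90% membership
with p ≤ 10⁻³) and by uniform null calibration over clusters of varying
size. The default significant set is the Holm-selected gene list from the
dose models; DSSA consensus genes can be substituted.

## Growth curves

OD readings every 15 minutes for 24 h (97 points). Background correction
subtracts each well's first reading (the pre-inoculation baseline); blank
wells are not modeled, as the correction reference was unspecified.
Growth is summarized by the trapezoid AUC (exact for constant and linear
curves, < 0.5% error against the analytic logistic integral at 15-minute
sampling), expressed as a percentage of the untreated control with
delta-method standard errors. ICx is read by linear interpolation at the
first crossing of the (100 − x)% level on the mean dose-response — no
four-parameter fit, matching dose-ladder practice — and returns nothing,
with a diagnostic, when no crossing exists. The exposure ladder for pooled
screens is 25%, 50% and 100% of the IC20. Negative AUCs (possible for
compounds that absorb at the reading wavelength) are kept and flagged.

## Orchestration and problem sizes

`pipeline.run_pipeline` chains simulate → normalize → dssa → dosemodel →
enrichment → network → growth with a single seed, records row counts and
content hashes in a manifest (identical config + seed reproduces identical
hashes), and fails with the missing stage's name when a dependency was
toggled off. All randomness flows through explicit `numpy` generators
seeded per stage; no global state.

Simulation sizes used by the test suite and the acceptance script are
chosen to make the statistical checks sharp while staying desk-scale:
2,000 genes for single-pool calibration, 500 screens of 200 genes for
family-wise error, 50 screens of 300 strains for DSSA operating
characteristics, 9,999 permutations/draws for permutation tests, 500-node
networks with 12-node planted modules. The full-scale worked example in
`analysis/` runs the complete 4,607-strain design.

## What the synthetic data does and does not establish

The generator reproduces the design's structure (replication, paired tags,
chip effects, dose–generation depletion) but not array-specific artifacts:
probe affinity differences, intensity-dependent dye or saturation effects
beyond smooth M–A trends, cross-hybridization, or strain fitness
heterogeneity in untreated growth. Passing tests therefore establish that
the statistical machinery is correct and calibrated under the stated
model, not that it would reproduce any particular genome-wide result from
real chips; the printed-table fixtures anchor the parts of the analysis
(consensus filtering, score conventions) that can be checked against
published numbers exactly.
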