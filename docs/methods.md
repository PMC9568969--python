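# Methods

`methylomp` implements a two-level Tukey-fence procedure for detecting an
*outlier methylation phenotype* (OMP) in a cohort of methylation array beta
values, together with the surrounding analyses such a study needs: probe
filtering, paired-tissue stability, hierarchical clustering with bootstrap
support, cross-individual outlier intersection with promoter gene calls, and
reference-based cell-type deconvolution. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The outlier model

All analyses operate on beta values β ∈ [0, 1] (methylated fraction per CpG
probe per sample). For each CpG *j*, the cohort's first and third quartiles
Q1ⱼ, Q3ⱼ define fences

    lowerⱼ = Q1ⱼ − 1.5·IQRⱼ,   upperⱼ = Q3ⱼ + 1.5·IQRⱼ,   IQRⱼ = Q3ⱼ − Q1ⱼ.

A sample is a **hyper** outlier at CpG *j* if βⱼ > upperⱼ, **hypo** if
βⱼ < lowerⱼ. Comparisons are strict on both sides: a value exactly on a
fence — including the degenerate case Q1 = Q3, where lower = upper — is not
an outlier. Degenerate-IQR probes are retained, since removing them would
silently change per-individual counts. Missing betas are never outliers;
they are tallied separately per profile so counts remain comparable.

At the second level the same upper fence is applied to the distribution of
per-individual outlier counts. An individual whose count strictly exceeds
that fence carries the OMP.

Design choices at this level:

* **Quantile convention.** Quartiles use linear interpolation between order
  statistics (the default of the mainstream numeric environments,
  including the R environment such analyses are typically run in). Because
  fence positions at n ≈ 28 samples are sensitive to the convention, the
  method is exposed as an enum (`linear`, `lower`, `higher`, `midpoint`)
  through every API and the CLI.
* **Candidates inside their own fences.** Both the per-CpG fences and the
  count fence include every individual, candidates included. This matches
  computing limits "within the data set" over the whole cohort. A
  leave-one-out mode for the count fence is available but not the default.
* **External confirmation.** When an external healthy cohort supplies the
  fences, per-CpG fences come from the reference samples at the shared
  probes, and the count fence from the reference cohort's own counts. Those
  reference counts are computed **leave-one-out** (each reference sample
  against fences from the remaining references) whenever the reference has
  ≥ 5 samples. The reason is a measurable small-sample asymmetry: for
  normal data and a 7-sample reference, a point *inside* its own fences is
  outside them ~4.2% of the time, while a *held-out* point is outside
  ~10.3% of the time. In-sample reference counts would therefore sit ~2.5×
  below the level of any healthy test sample and the count fence would flag
  everyone. Leave-one-out puts the reference counts at the same
  out-of-sample position as the test individuals (slightly conservative,
  since the LOO fences use one fewer sample). At exactly 4 reference
  samples LOO is impossible (fences need ≥ 4 values) and in-sample counts
  are used.

## Paired-tissue stability

Stability between an individual's cord-blood and saliva methylomes is the
squared Pearson correlation R² over the shared CpGs, complete-case per pair
(a CpG missing in either member is dropped for that pair only). R² is
literally the square of Pearson r — not a regression R² with intercept
variants.

The default 95% CI applies the Fisher z-transform to r, takes
z ± 1.96/√(n−3), and squares the back-transformed endpoints; if the
r-interval spans zero the R² lower bound is 0. The n here counts CpGs as
independent observations, which real methylomes violate (neighbouring CpGs
co-methylate), so the interval is optimistic on real data; a
probe-resampling bootstrap CI is available behind a flag. On synthetic
independent-CpG pairs the Fisher interval's measured coverage is ~0.95
(20,000-replicate estimate: 0.951).

The partitioned analysis splits the shared CpGs of an OMP individual into
their outlier set and its complement and reports R² for all/outlier/
non-outlier. The outlier set must be a nonempty strict subset of the shared
probes.

## Clustering

Samples are clustered on correlation distance d(a,b) = 1 − Pearson r over
shared non-missing probes, with average linkage (UPGMA) — the defaults of
the standard methylome-clustering stack; euclidean distance and
complete/single linkage are available as flags. The agglomeration is
implemented in-package with an explicit deterministic tie-break
(lexicographically smallest eligible cluster pair merges first); the scipy
implementation serves as an independent oracle in the tests, never as the
implementation.

Branch support is the plain bootstrap probability: resample probes with
replacement B times, rebuild the tree, and score each original internal
node by the fraction of replicates containing the same canonical leaf
bipartition. Multiscale-bootstrap AU p-values are a distinct published
algorithm and are deliberately out of scope; plain BP preserves the
qualitative conclusions (outlier branches, family clades) and is exactly
testable.

"Appears as an outlier in the dendrogram" is operationalized as: the k
samples whose singleton-join heights (height at which a still-unmerged leaf
first joins any cluster) are largest. Family co-clustering is reported as
whether each family's samples form an exact clade.

## Outlier intersection and gene calls

The CpGs outlier in *all* OMP individuals are partitioned into consistently
hyper (hyper in every individual), consistently hypo, and mixed; the three
classes always sum to the common count, which is why consistent-hyper +
consistent-hypo can fall short of the total. Only consistent CpGs feed gene
calling; mixed-direction CpGs are excluded.

"Promoter" means the manifest region groups TSS200, TSS1500, 5'UTR, 1st
exon (configurable). A gene is called hypermethylated when ≥ 3 of its
promoter CpGs are consistent outliers and ≥ 80% of those outlier CpGs are
hyper; hypomethylated analogously with a ≥ 5 CpG minimum. The asymmetric
minima are kept as the procedure's literal defaults; both are configurable.
The 80% fraction is taken over the gene's *outlier* promoter CpGs by
default; because the rule's wording is ambiguous, the alternative
denominator (all promoter CpGs of the gene) is available behind a flag. The
minimum fraction must exceed 0.5 so no gene can be called in both
directions. Pathway analysis itself is out of scope; the package exports
the gene lists.

## Deconvolution

Each sample's betas at a small marker panel (8 CpGs by default) are
modelled as a convex combination of cell-type reference profiles and solved
by simplex-constrained least squares (nonnegative, summing to 1; SLSQP with
an analytic gradient, then an exact renormalization so the simplex
constraint holds to machine precision). The estimator is pluggable in
principle; the reference profiles arrive as a user file, and a synthetic
two-type (leukocyte/epithelial) panel ships for fixtures. A rank-deficient
reference at the surviving markers is an error — the mixture would be
unidentifiable.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at a
scale where every property is testable in seconds:

* **Baselines.** Per CpG, a baseline mean μⱼ is drawn from a
  hypo/mid/hyper mixture with class centers 0.10/0.50/0.90 (weights
  0.40/0.20/0.40, spreads 0.03/0.08/0.03) — the bimodal shape of array
  methylomes.
* **Samples.** cord = clip(μⱼ + familyⱼ + noise, 0, 1) with within-cohort
  noise sd 0.03 and a family-shared per-CpG effect (sd 0.01) given to twin
  and sibling blocks; the default cohort has 28 individuals with three twin
  pairs and one twins-plus-sibling trio.
* **Cross-tissue correlation.** The saliva baseline νⱼ equals μⱼ with
  probability p and is re-drawn from the mixture otherwise — a shared
  tissue-discordance mechanism mirroring the observation that a fraction
  of CpGs are tissue-specific. p is solved in closed form from the target
  per-individual Pearson r using the empirical across-probe baseline
  variance, plus a per-CpG tissue offset (sd 0.02) and fresh noise. A pure
  noise-mixing scheme cannot reach r ≈ 0.8 here: with bimodal baselines
  (across-probe variance ~0.13) the decorrelating noise would need sd
  ~0.25 on the beta scale, which clipping at [0, 1] destroys. In the r → 1
  limit where even p = 1 is insufficient, a shared-noise weight κ (also
  closed-form) takes over; at r = 1, zero tissue offset and shared noise,
  the two matrices are identical. Re-drawn CpGs are flagged as the
  `blood_saliva_discordant` annotation subset, so the discordance
  exclusion applied before stability is semantically real. Realized
  per-pair r is within ±0.005 of target at 50,000 CpGs.
* **Planted OMP.** Chosen individuals receive a ±0.2 beta displacement at
  20% of CpGs (direction Bernoulli(0.5) per probe, applied in both
  tissues, recorded in the truth object). Displaced sets are drawn
  independently per individual. One planted default individual is a member
  of a twin pair, so the "outlier twin breaks the family clade" pattern is
  reproducible. An optional extra saliva-side noise at displaced probes
  (`omp_saliva_noise_sd`; the test fixtures use 0.15, sized so the
  outlier-subset R² falls to ~0.80 against ~0.91 at non-outlier CpGs,
  emulating the magnitude of the gap such longitudinal outlier analyses
  report) creates the outlier-vs-non-outlier stability ordering.
* **Markers.** Unless disabled, the 8 deconvolution marker CpGs are
  overwritten with true leukocyte/epithelial mixtures (cord leukocyte
  fraction U(0.88, 0.99), saliva U(0.55, 0.90), noise sd 0.01), recorded
  in the truth object.
* **External reference.** Unplanted samples drawn from the same per-CpG
  baselines, 7 by default.

What the generator does **not** emulate: spatial correlation along the
genome, chip/batch effects, detection-p-value structure (failures arrive as
missing marks), age-dependent drift, ancestry structure, and realistic
per-gene clustering of disrupted CpGs. Consequences: (i) passing recovery
tests show the *procedure* is correct and calibrated, not that real
cohorts separate this cleanly; (ii) Fisher CIs are well-calibrated here
precisely because synthetic CpGs are independent — on real methylomes they
are anti-conservative; (iii) with independent displaced sets, only
omp_frac³ of CpGs are common to three planted individuals and ~25% of
those are direction-consistent, so promoter gene calls on a default
synthetic cohort are typically zero — the gene rules are exercised by
constructed fixtures at their decision boundaries instead.

## Problem sizes and numerics

Simulation-backed checks use 28 individuals × 20,000 CpGs (50,000 for
stability recovery, where the ±0.01 tolerance needs the larger panel), 20
seeds for recovery, 100 cohorts for null calibration, and B = 100 bootstrap
replicates for clustering — sizes at which every documented property holds
with wide margin and the whole suite runs in a few minutes on one core.
Determinism is end-to-end: one master seed fans out to per-stage seeds by
hashing the stage name, and two runs with the same config produce
byte-identical output directories (verified by SHA-256 in the run
manifest). Quantile computations delegate to `numpy.quantile`; fences are
validated against hand-rolled order-statistic interpolation in the tests.
Beta-range validation rejects values outside [0, 1] at load time; NaN is
the single missing representation internally and `NA` on disk.

## Known limitations

* The Tukey count fence at n = 28 is sensitive to the quantile convention;
  conclusions should be checked across conventions (the enum makes this a
  one-flag change).
* Fisher-z CIs assume independent CpGs (see above).
* Bootstrap probabilities are not AU p-values and are known to be biased
  low for large clades.
* The external-reference count fence is slightly conservative by
  construction (LOO fences use n−1 samples).
* Twins are treated as independent draws when computing fences.
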