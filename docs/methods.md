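# Methods

## The statistic

For a kinase with substrate phosphosites i = 1..m on the array, substrate
prediction scores xᵢ > 0 and measured log2 fold changes log2FCᵢ, the
activity score in one condition is

    s_w = Σ xᵢ·log2FCᵢ / Σ xᵢ
    Z   = (s_w − p̄)·√m / SD

with p̄ and SD the mean and sample standard deviation (n−1 denominator) of
the log2 fold changes of **all** phosphosites in the same condition column.
This is the classic KSEA form with the unweighted substrate mean replaced
by a prediction-score-weighted mean: substrates with stronger
kinase–substrate evidence contribute proportionally more.  With all
weights equal the statistic reduces exactly to unweighted KSEA (a tested
invariant).

Modelling assumptions, and what follows from them:

* Fold changes of non-substrates form the background; under no kinase
  activity, s_w is an average of background values and Z is approximately
  standard normal.
* p̄ and SD are computed per condition column, never pooled across columns
  or chips.  Consequence: Z is invariant to adding any constant to a
  column or scaling it by any positive constant, so column-wise
  normalization artefacts cannot move the scores (tested to 1e-10).
* m is recomputed per column from the substrates that actually have a
  measured fold change there; missing values are never imputed.  A kinase
  with no usable substrate in a column yields an explicitly missing score,
  rendered `✕` in summary tables.

## One-tail p-values and their calibration

The p-value is the standard-normal tail beyond the observed score in the
score's own direction: p = P(N(0,1) ≥ |Z|), symmetric in ±Z.  This is a
*directional* one-tail test selected by the data, so its null flag rate at
level α is the two-sided rate: a truly inactive kinase satisfies p < .05
whenever |Z| > 1.645, which happens for ≈ 10% of null scores, not 5%.
The package reports this honestly rather than halving α internally: the
global-null simulation measures the flagged fraction at ≈ 0.10 while the
same z scores pass a Kolmogorov–Smirnov test against N(0, 1) (the weighted
mean widens Z by Σxᵢ²·m/(Σxᵢ)² ≈ 1.10 in variance, which the substrates'
own share of the background p̄ almost exactly offsets at array scale).
Users who need a strict 5% null rate should either test at α/2 or use the
Benjamini–Hochberg adjusted column (`p_adj`, computed per condition over
the non-missing kinases with statsmodels) that is emitted alongside but
never drives the arrow/marker reports, which follow the raw-p convention
of the underlying assay literature.

A kinase is "significant" if p < α (default .05) in at least one
condition; the selection can then be intersected with an expressed-gene
allow-list (case-insensitive symbol match) to drop kinases not present in
the cell system.

## Mapping rules

* Per phosphosite, only predictions scoring **strictly** above 300 survive,
  then at most the top 25 (PTK) / 50 (STK) kinases per site, ordered by
  descending score.  Ties at the cap are broken by ascending kinase symbol
  — the wording defines no order and reproducibility requires a total one.
* The filter is per phosphosite, so a kinase's total substrate count may
  exceed the cap; the cap bounds kinases per site, not sites per kinase.
* The same (kinase, site) pair arriving from several source databases is
  collapsed to the maximum score (strongest evidence, each substrate
  counted once); exact ties resolve by a fixed source priority
  (PhosphoNET > UniProt > PhosphoSite > synthetic).
* Phosphosite identifiers are opaque strings matched exactly and
  case-sensitively between fold-change matrices and prediction tables.
* `min_substrates` defaults to 1; single-substrate scores are statistically
  fragile (Z = (fc − p̄)/SD), so the floor is configurable.

## Contrasts against a reference agonist

On the log2 scale, fc(t vs reference) = fc(t vs vehicle) − fc(reference vs
vehicle) site-wise, computed on replicate means (replicates are not paired
across treatments, so per-replicate pairing is not attempted).  The full
pipeline reruns on the rebaselined matrix — in particular p̄ and SD are
recomputed there, since the contrast distribution, not the vehicle one, is
the relevant background.  With complete data this is algebraically
identical to normalizing mean intensities directly against the reference
arm (tested to 1e-10; with missing data the two differ only in sites
missing in the vehicle arm alone).

## Categorical encoding

Arrow bins have half-width 1.21 with edges at ±1.21·k: `-` covers
(−1.21, 1.21), k arrows cover [1.21·k, 1.21·(k+1)) up to three arrows,
and |z| beyond 4.84 still maps to the outermost label — the printed
ranges describe observed data extent, not a domain bound.  Positive bins
are closed on the left, open on the right (mirrored for negative): shared
printed endpoints cannot all be closed, and half-open is the standard
resolution.  Markers: `•` p < .05, `••` p < .01, `•••` p < .001, strict
inequalities.  Heatmap rows are ordered by descending mean |z| (ties by
symbol) — a deterministic stand-in for unspecified clustering.

## The synthetic generator

`SimulationParams` defaults define the emulated design: 4 treatments
(vehicle, reference agonist, two biased derivatives) × 2 durations
(10, 120 min) × 4 replicates; 196 (PTK) or 144 (STK) phosphosites; 60
candidate kinases with 5–25 predicted substrates each and prediction
weights uniform on (300, 1000]; baseline 9.0 log2 units with a per-site
offset of SD 1.0 (realistic between-peptide fluorescence heterogeneity)
and replicate noise of SD 0.25 log2 units (Gaussian on the log2 scale,
i.e. log-normal fluorescence noise).  10% of sites are oversubscribed past
the per-site top-K cap so the mapping filter is exercised on both sides of
its boundary.

An injected kinase activity δ (log2FC units) shifts each of its substrate
sites by δ·w/Σw — the kinase's prediction-score share of all kinases
predicted for that site.  This makes the weighted mean the efficient
estimator of δ, rewarding the weighted statistic over the unweighted one,
but it also means a site shared by many kinases dilutes every one of
them: at the default density (~6 co-predicted kinases per site, more on
oversubscribed sites) an injected δ = 1.0 reaches a substrate as ≈ 0.17
log2 units, and recovered sensitivity at p < .05 plateaus near 0.87 for
5 active kinases per condition with 15–25 substrates each at noise 0.25.
Substrate sharing also leaks activity into co-predicted kinases, which is
why a recovery experiment's false-positive rate among uninjected kinases
(≈ 0.07) sits slightly above what SD inflation alone would give; the
injected kinases still rank in the top ~7% of their columns on average.
Sensitivity decreases monotonically with replicate noise (tested).

What the generator does **not** emulate: instrument-side kinetics
(exposure series, read cycles), peptide-specific antibody efficiency,
heavy-tailed or correlated replicate noise, and real kinase–substrate
network topology (predictions are random bipartite draws).  Passing
recovery tests therefore demonstrates correctness and calibration of the
*statistics* under the stated model, not performance on real arrays.

"Kinase not found" cells are simulated by masking a kinase's substrates in
selected conditions (`mask_substrates`), producing per-condition missing
scores exactly as per-dataset substrate QC would.

All randomness flows through `numpy.random.default_rng` seeded on
(seed, stream) pairs — prediction tables, truths, intensities and
multi-run experiments are each independently reproducible, and derived
per-run seeds stay below 2³¹.

## Numerical and format choices

* CSV dialect: UTF-8, comma-separated, mandatory header, `NA` as the only
  missing token (readers never coerce missing to zero), reals at 12
  significant digits — round-trip error is below test tolerances (1e-11
  relative).
* Matrix files carry `#chip_type=` / `#baseline=` metadata lines so
  vehicle-normalized and rebaselined matrices cannot be confused.
* Degenerate inputs fail loudly: constant fold-change columns, columns
  with fewer than two measured sites, empty score tables, empty
  allow-lists, designs lacking a vehicle arm or with fewer than two
  replicates.
* Bin-edge arithmetic adds a 1e-9 tolerance before flooring so exact
  decimal edges (e.g. z = 2.42) land in the documented bin despite binary
  representation.

## Problem sizes used in the shipped checks

The calibration and recovery checks run at the full default design: null
calibration pools 7 simulated experiments (2,520 kinase-condition scores);
recovery uses 50 runs at noise 0.25 plus 20-run arms at noise 0.5 and 1.0.
The whole suite and the reproduction script each complete in well under a
minute on a single CPU.
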