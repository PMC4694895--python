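# Methods

This note documents the models, conventions and design choices behind
`glioscreen`, in the order the pipeline runs them.

## Study design the package encodes

The pipeline is shaped around a two-panel stem-cell culture comparison:
nine case (tumor stem-cell) cultures against five control (normal neural
stem-cell) cultures on log2 expression microarrays, with verification in an
independent 7-case / 4-control qPCR panel, 7-case / 2-control westerns,
growth and sphere assays on the case cultures, public-cohort survival
tables (~200 glioblastoma patients with subtype labels) and a curated
protein-interaction table. The synthetic-data module defaults reproduce
exactly these shapes so that the packaged defaults *are* the study
conditions rather than arbitrary toy sizes.

## Consistency filter

A gene passes iff its log2 expression is strictly below the threshold
(default 0) in every control sample and strictly above it in every case
sample. Values exactly at the threshold exclude the gene. The rule is an
all-or-nothing screen: it has no notion of significance and trades power
for candidates with a clean on/off contrast, which is the appropriate bias
when the goal is therapeutic targeting (the target should be absent from
the healthy counterpart). Two properties are worth stating precisely:

* the selected set is invariant to sample and gene order;
* selection is *not* monotone in the threshold — a gene passes exactly when
  the threshold lies in the open interval (max control value, min case
  value), so the valid structural property is convexity in the threshold,
  and that is what the tests assert.

Fold changes are `2^(case mean − control mean)`; published overview
tables print linear fold changes, and this is the standard definition
consistent with log2 input. For probe-level arrays a deterministic
max-mean-probe collapse to genes is provided and applied before filtering.

## Co-expression, modules, PCA

Distances are `1 − r` (Pearson); a squared-Euclidean option exists for
sample-level views. Trees are UPGMA (average linkage). The linkage itself
is scipy's; to make partitions order-invariant and tie-breaks fixed, items
are sorted lexicographically by id before linkage, so any permutation of
the input maps to the same internal problem. `cut` relabels the k clusters
I, II, III… by the alphabetically first member. PCA operates on the
samples × genes layout with per-gene centering (plain SVD scores).

One caveat the tests make explicit: on a case/control matrix the
group-mean shift dominates every selected gene's profile, so all
candidates are mutually highly correlated and module structure within the
candidate set is only weakly identified. Module extraction is meaningful
on panels without a dominating group contrast (e.g. tumor-tissue cohorts),
which is how the pipeline's end-to-end test treats it (module members must
stay together; exact module boundaries are not asserted there).

## qPCR: efficiency-corrected ratios and the reallocation test

Technical replicates are averaged to one Cq per (gene, sample) before any
group statistic; randomization reallocates samples, never replicates
(pseudo-replication guard). The ratio is

    ratio = E_t^(ΔCq_t) / G,   G = geometric mean over references of E_r^(ΔCq_r)

with `ΔCq = mean Cq(control) − mean Cq(case)` and per-gene efficiencies
`E ∈ (1, 2]` (default 2; then the ratio is `2^−ΔΔCt`). Aggregating multiple
reference genes by the geometric mean is the standard relative-expression
convention when several housekeeping genes are used. All control cultures
are pooled as a single reference group.

The fixed-reallocation test reassigns case/control labels with group sizes
fixed and compares `|log ratio|` against the reallocation distribution.
Implementation note: for complete designs (every sample measured for the
target and all references) the log ratio equals a difference of group means
of the per-sample score
`v_s = Cq_t,s·log2 E_t − mean_ref(Cq_r,s·log2 E_r)`, which makes exhaustive
enumeration a single matrix product. Enumeration is used when the number of
distinct allocations is within the iteration budget (default 2000),
Monte-Carlo otherwise with `p = (1 + hits) / (1 + draws)`. The observed
allocation is always counted, so p is never 0. Because the test is a valid
permutation test, its type-I error is at or below the nominal level up to
discreteness; the acceptance suite checks ≤ 0.06 at α = 0.05 over 2000
null genes. Sample-wise Cq shifts (loading differences) cancel through the
references exactly when target and reference efficiencies coincide; with
unequal efficiencies the cancellation is approximate, which is inherent to
the efficiency-corrected model, not an implementation artifact.

Calls: UP if ratio > 1 and p < α, DR if ratio < 1 and p < α, else NS
(default α = 0.05).

## Western quantification and RNA–protein correlation

RPE = (band − band background) / (loading control − its background) per
lane. A band falling below its local background means the protein is
effectively absent: the RPE is recorded as 0 with a QC flag rather than an
error (down-regulated proteins in control-normalized panels produce these
legitimately). A non-positive loading-control net intensity is an error
naming the lane, since the lane cannot be normalized.

RNA–protein agreement per gene is the Pearson coefficient of the qPCR and
RPE profiles over shared samples (≥ 3). Summary aggregates over a gene set
report mean and **population** SD (divisor n); that convention reproduces
the packaged overview table's printed 20-gene aggregate (0.55 ± 0.41) and
nine-gene module aggregate (0.75 ± 0.12) exactly at two decimals. For the
three genes with negative RNA–protein correlation the table prints
magnitudes; the sign is restored (−) when `signed=True`. The printed
spread of that three-gene aggregate (0.27) is not derivable from the
printed per-gene values under any SD convention (population gives 0.2254,
sample 0.2761); it was evidently computed upstream from unrounded
coefficients, and the tests assert the value derived from the table.

The targeted-proteomics clustering appends per-sample assay features to the
RPE matrix — sphere-forming ability normalized to [0, 1] (control baseline
→ 0, maximum → 1) and reciprocal doubling time — and clusters rows with
the same Pearson/UPGMA machinery.

## Growth assays

`PDT = t·log 2 / (log Nt − log N0)`; the base cancels, counts can be
rescaled freely, `Nt = N0` is singular, and a shrinking culture yields a
negative PDT flagged as such. Multi-passage series are summarized as
mean ± population SD per culture. Sphere assays report mean/SD of per-well
counts and per-sphere diameters. Assay cross-correlation is plain Pearson
on matched cultures; any transform (e.g. 1/PDT) is the caller's.

## Survival stratification and comparison

Patients are z-scored per gene and grouped by one of two documented modes:

* **cluster** (default of `stratify`): Pearson-distance UPGMA over patient
  z-profiles cut at k, clusters ranked by mean module z-score and labelled
  low / intermediate / high. This mode compares *profile shapes*: Pearson
  correlation centers each patient's vector, so it is blind to a uniform
  level shift across the module.
* **tertile**: patients ranked by mean z and split into k near-equal
  groups. This mode measures *level* directly.

Because the planted (and clinical) question is about concurrent
up-regulation — a level property — the pipeline's survival stage and the
end-to-end recovery checks use the tertile mode; the cluster mode is the
primary contract for pattern-defined groups and is tested on
pattern-separated fixtures. The group with the largest mean z is always
"high".

The Kaplan–Meier estimator processes deaths before censorings at tied
times (a patient censored at t is still at risk for deaths at t). The
median is the smallest event time with S(t) ≤ 0.5, undefined (None) if S
never reaches 0.5. The Gehan–Breslow–Wilcoxon statistic is the weighted
log-rank with weight equal to the total number at risk at each event time,

    Z = Σ_i n_i (d_{1i} − d_i n_{1i}/n_i),
    Var = Σ_i n_i² d_i (n_{1i}/n_i)(1 − n_{1i}/n_i)(n_i − d_i)/(n_i − 1),

with `Z²/Var` referred to χ²(1), two-sided; early deaths dominate, which is
the intended emphasis when curves separate early. An `exact=True` mode
enumerates all fixed-size reallocations of patients between the groups and
returns the reallocation p of the statistic (observed counted); it is the
reference for small groups, where the χ² approximation is coarse. The
default p remains the χ² reference. The implementation is authored here
(the exact mode and tie conventions are part of the contract); an
established survival library's Wilcoxon-weighted log-rank serves as an
independent oracle in the tests.

The probe-level screen fits a univariate logistic regression per probe
(maximum likelihood, Wald two-sided p); a constant probe is reported as
slope 0, p 1 (it carries no information), and complete separation is
flagged with no p reported. Benjamini–Hochberg step-up adjustment controls
FDR at q (default 0.10).

## Interaction graphs

Edge lists build undirected graphs with self-loops dropped and duplicates
collapsed; edges carry a type (protein-protein by default), free-text
evidence, and a `mediated` flag. The packaged curated interaction table
expands each documented pair as: direct rows → the edge (a, b)
(`mediated=False`); every intermediary x of an indirect row → edges (a, x)
and (x, b) (`mediated=True`). A pair documented both ways keeps the direct
flag.

`common_interactants(g, a, b)` is the shared-neighbor intersection minus
the endpoints. With `mediated_only=True` only neighbors reached through
mediated edges on both sides count — the convention matching how curated
tables enumerate a pair's intermediaries. The distinction matters: in the
packaged table, ubiquitin C binds both STAT3 and EZH2 directly, so the
plain intersection for that pair is 14 while the documented-intermediary
count is 13; for EGFR–PBK both conventions give 11. The default hub rule
(degree > mean + 1 population SD, strict so regular graphs have no hubs)
is a package convention — the threshold is not canonical and is
overridable via `min_degree`.

## Synthetic data

`simulate_expression` plants consistent genes at +2 / −2 log2 (cases /
controls) around a zero background with Gaussian noise (SD 0.5 — a
realistic per-probe spread for log2 arrays); module members additionally
share a latent per-sample factor with loading √ρ, giving pairwise
correlation ≈ ρ. `simulate_cq` places case samples `log2(F)/log2(E)`
cycles below the control baseline for planted fold change F, adds
per-sample loading shifts (which cancel through references at equal
efficiencies) and replicate noise. `simulate_bands` multiplies planted RPE
by a lognormally varying loading-control intensity plus additive
background. `simulate_survival` draws exponential times for two planted
arms (baseline median 383 days; hazard multiplied for the high arm,
default 2) with independent exponential censoring calibrated to the
requested rate in the low arm; module-gene expression separates the arms
with gene-specific shift weights (0.5×–1.5× around shift 1.5, noise SD 1)
so both level- and pattern-based stratification have signal.
`simulate_growth` produces noiseless exponential growth at planted
doubling times with Poisson sphere counts proportional to growth rate;
`simulate_edges` grows a preferential-attachment graph (heavy-tailed
degrees). All generators derive independent streams from the single config
seed; identical configs give identical outputs.

What the generators deliberately do **not** emulate: probe-level array
artifacts, batch effects, normalization residuals, non-exponential hazard
shapes, subtype structure, or biologically realistic interaction topology.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative models, not robustness to real-data pathologies.

## Problem sizes used by the checks

The heavier verification runs are sized for a single CPU: the
filter-vs-oracle equivalence uses a 10 000-gene, 9 + 5-sample matrix; the
survival power check runs 200 replicates at 200 patients per arm (hazard
multiplier 2), requiring the high arm's KM median to be shorter in ≥ 95%
and GBW p < 0.05 in ≥ 80% of replicates; the qPCR null calibration uses
2000 simulated null genes in the 7 vs 4 design with two references.

## Known limitations

* The consistency filter is sensitive to a single outlying sample by
  design; no robust variant is provided.
* The reallocation test requires complete designs (every sample measured
  for target and references); incomplete panels must be subset first.
* Cox modelling, interval censoring, WGCNA-style soft thresholding,
  standard-curve efficiency estimation and image densitometry are out of
  scope; inputs are expected at the level of Cq values, band intensities
  and cell counts.
* The curated interaction table is a static snapshot; live database
  queries are intentionally replaced by file input.
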