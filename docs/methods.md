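# Methods

## Lifetime comorbidity model

A patient's record is reduced to the **set** of distinct 3-digit ICD-9-CM
categories over all visits ("lifetime" history).  Deduplication controls
for chronic diseases recorded at every encounter; temporal order is
deliberately discarded (the networks are undirected — no causal claim).
Within a group of *n* patients, each unordered pair of diagnoses gets

* `SCI_ij = c_ij / sqrt(c_i * c_j)` — the cosine of the two binary
  indicator vectors, in [0, 1], invariant to uniform replication of the
  sample;
* `phi_ij = (n c_ij − c_i c_j) / sqrt(c_i c_j (n−c_i)(n−c_j))` — the
  Pearson correlation of the indicators, with chi-squared significance
  `n·phi² > χ²₁(1−α)` (6.6349 at α = 0.01).

Pairs that never co-occur carry no information and are not tabulated.
Degenerate margins (a code present in all patients) leave phi undefined
(NaN, never significant); SCI is still defined.

### Cutoff calibration

Phi significance grows mechanically with *n*, so it cannot weight edges in
groups of different sizes, but on the *pooled* dataset it pins down an SCI
threshold: the cutoff is the k-th largest SCI where k is the number of
phi-significant pairs at the 1% level, so that #{SCI ≥ cutoff} = k.  When
the k-th order statistic is exactly duplicated no cutoff attains the
equality; the k-th order statistic is returned and the excess is bounded by
the tie count (observed: 0–2 pairs in ~250,000 on pooled synthetic runs).
The study population this pipeline follows arrived at 0.04, which is the
pipeline default; calibration is re-run with `sci_cutoff="calibrate"`
(pooled by default, per group behind `per_group_calibration`).

### Filters and network assembly

Per group, in pipeline order: (1) pairs with `c_ij` below the mean
co-occurrence of co-occurring pairs (`c_ij ≥ 1`) are removed — zero pairs
are excluded from the mean, since a pair that never occurs is not an
"occurring" pair; ties at the mean are retained; (2) remaining pairs with
SCI ≥ cutoff (ties retained) become edges.  Both steps are per-pair
predicates, so their order does not affect the final edge set.  The node
set of a network is every diagnosis observed in the group — isolated
diagnosed codes count toward node totals and degree averages (`2E/N`),
matching how the source tables report 884–891 nodes out of a ~900-code
universe.

### Group comparison and organ aggregation

Degree and weighted-degree distributions are compared by one-way ANOVA with
nodes as observations within each group network — the only reading that
yields a single F statistic over several networks.  Densities are compared
by a two-proportion chi-squared test with successes = edges and trials =
N(N−1)/2.  Organ-level networks sum SCI over all diagnosis edges spanning
two of the 18 ICD-9-CM chapters; within-chapter sums are tracked as
chapter self-weights (reported, not drawn) so total weight is conserved
exactly.  Chapter pairs are highlighted when aggregate weight is strictly
greater than 10 (threshold configurable).  The chapter table ships as a
data file; nervous system (320–359) and sense organs (360–389) are kept as
separate chapters 6 and 7 because the 18-class scheme distinguishes them,
although ICD-9-CM formally groups 320–389.

## Ingest rules

* Codes are truncated to their 3-digit category (zero-padded).  V- and
  E-prefixed supplementary codes fall outside the 001–999 organ-system
  scheme and are dropped with counts; malformed codes are skipped with a
  logged warning and counted.
* Chapter 17 (general symptoms, 780–799) never reaches the comorbidity
  stage: visits carrying only symptom/unclassifiable codes are removed
  whole, and symptom codes on mixed visits are dropped individually.  The
  source procedure states only that symptom-only visits are disregarded;
  dropping symptom codes everywhere is our reading, consistent with the
  exclusion of class 17 from all downstream tables.
* Race labels are opaque, case-normalised strings.  Patients with more
  than one distinct non-missing label are removed entirely (recording
  error); patients with no label at all are removed; a single label plus
  missing entries is kept and filled.
* Matched comparison uses simple random sampling of **patients** without
  replacement, every group down to a common size (the smallest group by
  default, which passes through whole).  Each group samples from an
  independent stream derived from (seed, group rank), so adding a group
  never perturbs another group's sample.  Whether the original study
  stratified its equal samples is unstated; we use simple random sampling.
* Every dropped row, visit and patient is accounted for in a drop report
  (input rows = retained + dropped, by reason).

## Synthetic EMR generator

The generator emulates the *structure* of a large multi-group EMR — it is
a ground-truth test bed, not a clinical simulator.

**Lifetime layer.**  Codes outside planted pairs are independent Bernoulli
draws at their base prevalence.  Each planted pair `(a, b, p_joint)` is
drawn from the four-point coupling on {both, a-only, b-only, neither} with
joint probability exactly `p_joint` and exact marginals, so the pair's
generative SCI is `p_joint / sqrt(p_a p_b)` in closed form.  Feasibility
requires `p_joint ≤ min(p_a, p_b)` and `p_a + p_b − p_joint ≤ 1`; violations
raise a configuration error naming the pair.  Planted pairs within a group
must use disjoint codes (keeps all marginals exact); three-plus-way planted
dependence is out of scope.  Patients drawing an empty set are redrawn:
conditioning on non-emptiness scales every event probability by the same
constant, so every pair's SCI is unchanged exactly, while marginals inflate
by 1/P(non-empty) — negligible (<1e-4 relative) at the default universe
sizes.

**Visit layer.**  Visit counts are `1 + Poisson(mean − 1)` so every patient
visits at least once.  Lifetime diagnoses are scattered coverage-first over
visits (each visit records at least one code); visits beyond the number of
distinct diagnoses record a general-symptom code (780–799), as real
encounters do — these are then removed by the ingest symptom filter, so
post-cleaning visit means sit slightly below the generator mean for
patients with few diagnoses.  Chronic codes (a configurable set; default
includes 250, 401, 272, 296, 414, 493, 585, 715) are re-recorded at every
visit after first appearance.  Recorded code strings randomly carry 4th/5th
digits to exercise truncation.  Ages are normal, truncated to [0, 110].
Determinism: a fixed scenario seed yields byte-identical output; each group
draws from a stream derived from (seed, group index), overridable per group.

**Bundled scenarios.**

* `five_group_scenario(scale, seed)` — five groups with the published
  summary statistics of the study population (sizes scaled down; visit
  means 2.57–4.83, mean distinct diagnoses 3.32–5.86, group-specific ages)
  over an 899-code universe spanning all 18 chapters, plus planted
  chapter-block structure whose strength ordering mirrors the study's
  qualitative findings (African American strongest, Hispanic weakest).
  Base prevalences follow a lognormal profile (σ = 0.9) scaled to each
  group's mean diagnosis count and capped at 3% per code.
* `two_group_block_scenario(seed)` — two equal 20,000-patient groups, only
  group A carrying a 50-pair chapter-(1,9) block at generative SCI 0.25
  (aggregate organ weight ≈ 12.5, above the highlight threshold of 10);
  group B has identical marginals with no coupling (background weight ≈
  0.2–0.4).
* `stability_scenario(seed)` — a single 100,000-patient group for
  subsampling-stability experiments; see below.

**What the generator does not emulate.**  Real prevalence spectra with very
common categories (hypertension at 15–30%), age- and sex-dependent
prevalence, higher-order disease clusters, visit-level temporal dynamics,
coding drift across hospitals.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the *method* under known
structure, not clinical validity on any real cohort.

## Numerical and design notes

* Pair counting is sparse matrix algebra (`triu(XᵀX)` on the
  patients×codes incidence matrix); it is tested for exact agreement with
  a quadratic brute-force oracle.
* The vectorised pair table and the scalar `sci`/`phi` functions are
  cross-checked against each other; phi is additionally checked against
  the Pearson correlation of the raw indicator vectors.
* SCI invariance under k-fold patient replication holds to machine
  precision (bitwise for powers of two; ~1 ulp otherwise, from
  `sqrt(k²·c_i·c_j)` vs `k·sqrt(c_i·c_j)`).
* **Subsampling stability scale.**  Network stability under subsampling
  requires every pair's integer co-occurrence threshold
  `ceil(0.04·sqrt(c_i c_j))` to sit several Poisson standard deviations
  above the chance co-occurrence rate at the *smaller* scale.  Codes that
  are too rare cross the cutoff with 2–3 chance co-occurrences; codes that
  are too common have chance rates `n·p²` growing faster than the
  threshold `0.04·n·p`.  On a heavy-tailed 900-code universe at 20,000
  patients this background contributes hundreds of spurious edges that
  vanish at 100,000 patients, so the density comparison fails for reasons
  unrelated to SCI itself — the original study avoided this regime by
  calibrating on ≥157,880 patients per group.  `stability_scenario`
  therefore uses a focused 150-code panel at a uniform 0.9% prevalence
  (the resolvable band at a 20,000-patient subsample is roughly 0.9–1.1%)
  with 60 planted pairs at generative SCI 0.3; there the full and
  20%-subsampled networks are statistically indistinguishable in density
  in ≥90% of seeds, the property the robustness check asserts.
* No multiple-testing correction is applied to the phi significance used
  in calibration (plain 1% level, α configurable), replicating the source
  procedure.
* Simulation sizes in tests and the acceptance script (100,000 patients
  for stability, 20,000 per group for recovery, 500-patient oracle
  instances, 50/20-seed repetitions) were chosen so each property is
  measured at the scale its statement prescribes while a full run stays in
  the minutes range.
* Plotting is limited to standard network exports (GraphML + edge lists;
  spring layouts render fine in any graph tool); the anatomical body-map
  layout used in the source figures is out of scope.

## Known limitations

* ICD-9-CM only; no ICD-10 crosswalk.
* The 18-chapter boundary table follows ICD-9-CM convention; the source's
  own supplementary boundary table was not available for confirmation.
* Visit dates are treated as an ordering only; no time-window analyses.
* Equal sampling is unstratified; matched analyses on age/visit-count/time
  are supported in principle by the same mechanism but not implemented as
  named experiments.
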