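# Methods

`oncomodules` implements an end-to-end framework that converts
tumour-specific causal assignments between somatic genome alterations
(SGAs) and differentially expressed genes (DEGs) into (i) modules of
co-regulated DEGs with their dominant driver SGAs and (ii) patient
subgroups with distinct survival. This note describes each stage's model,
its tunable parameters, the synthetic cohorts used to exercise it, and the
numerical choices made where the design was open.

## Input model

The upstream causal-inference step is consumed purely as a data contract: a
table of `(tumour, sga, deg, posterior)` rows in which, within one tumour,
every DEG has exactly one SGA assigned as its cause (the *one-cause rule*),
and each SGA may cause many DEGs. A companion observation table records
which genes carry a somatic mutation or copy-number alteration in which
tumour. The inference algorithm itself is out of scope; its posterior
calibration is represented by a supplied scalar floor.

## Filtering standards

Four successive standards turn raw assignments into significant drivers and
relationships:

1. **Posterior floor** — keep assignments with posterior strictly above
   `posterior_floor` (default 0.5). The floor stands in for a permutation
   calibration that requires re-running the upstream inference; it is a
   plain parameter (strict `>`).
2. **Tumour-level driver call** — an SGA is a driver *in a tumour* if it
   causes ≥ `min_degs_per_driver` (5) distinct DEGs there.
3. **Significant driver** — driver in ≥ `min_driver_tumours` (30) tumours
   **and** in ≥ `min_driver_fraction` (25%) of the tumours where the SGA is
   observed (conjunction).
4. **Significant relationship** — the SGA is a significant driver **and**
   the pair is assigned in ≥ `min_relationship_tumours` (50) tumours **or**
   in ≥ `min_relationship_fraction` (20%) of the SGA's driver tumours
   (disjunction).

Count and fraction thresholds are inclusive (≥). Duplicate
`(tumour, sga, deg)` rows collapse to the maximum posterior with a warning;
one-cause violations are rejected. One subtlety worth knowing: the pipeline
as a whole is *not* monotone in every threshold — raising the posterior
floor shrinks the driver-tumour denominator of standard 4's fraction
branch, which can newly qualify a surviving pair. Driver calls and
significant drivers are monotone; relationships are monotone in the
relationship thresholds.

## Co-regulation network

Nodes are DEGs appearing as significant-assignment targets in strictly more
than `min_node_fraction` (10%) of the tumours that retain at least one
significant assignment. A *co-regulation instance* is a
`(tumour, sga, DEG pair)` triple in which both DEGs are assigned to that
SGA in that tumour; an SGA causing m kept DEGs in a tumour contributes
m(m−1)/2 instances. Edge weight `W_ij` is the number of *distinct tumours*
with an instance for the pair (under the one-cause rule a tumour cannot
repeat a pair). All instances are retained as edge provenance for driver
attribution. An optional `min_edge_weight` reproduces the stricter reading
where edges themselves must recur in a fraction of tumours; the node-filter
construction is the default because it is the operative procedural
description.

## Spectral consensus modules

Weights become pseudo-distances `D_ij = 1/W_ij` (∞ for absent edges, 0 on
the diagonal) and then Gaussian-kernel affinities

    A_ij = exp(−D_ij² / 2σ²),

so frequently co-regulated pairs approach affinity 1 and rare ones are
suppressed (the kernel is monotone in `W`). The bandwidth σ defaults to the
median of the finite off-diagonal pseudo-distances (`sigma_quantile` 0.5);
fixed presets may be supplied instead. From `A`, the degree-normalized
operator `D_deg^{-1/2} A D_deg^{-1/2}` is formed, its k
largest-eigenvalue eigenvectors are row-normalized to the unit sphere, and
k-means with plain random centre initialization (seeded; `n_init=1`,
max 300 iterations, tol 1e-6) yields one partition. Zero-degree nodes are
routed to a sink module labelled k+1 instead of crashing the degree
normalization. Eigenvectors are sign-fixed (first component of magnitude
> 1e-12 made positive) so repeated runs are bitwise identical; repeated
eigenvalues are ordered by descending eigenvalue.

Single runs are initialization-dependent by design, so the working
partition is a consensus: 100 runs (all nodes, no resampling), consensus
entry = co-clustering frequency, and the reported labels come from
average-linkage hierarchical clustering of 1 − consensus cut at k. The
module count is chosen from consensus stability, scored as 1 − PAC with
ambiguity band [0.1, 0.9]. Scanning k upward, the scan stops at the first
*drop* in stability (more than `drop_tolerance` = 0.005 below the running
maximum); within the pre-drop candidates meeting `stability_floor` (0.75)
the chosen k is the *smallest* member of the trailing stability plateau.
The plateau rule matters: over-splitting a cleanly separated module system
can be exactly as stable as the true partition (the extra embedding
direction splits one module the same way in every run), so "largest stable
k" would systematically over-split; stability saturates at the true k and
the plateau's first member recovers it. A coarse-then-fine variant
(`select_k_coarse_fine`) scores a coarse grid (5, 10, 15, 20) first and
then scans the bracket around the most stable coarse value.

## Module annotation

For each module, provenance instances whose DEG pair lies wholly inside the
module are grouped by SGA; each instance has exactly one SGA, so the
per-module proportions sum to 1. An SGA is *dominant* when its share is
strictly greater than 10%. Gene-set overlap uses the upper-tail
hypergeometric p-value `P(X ≥ overlap)` with the gene universe defaulting
to the network's nodes (configurable; the choice of universe is a genuinely
open design point — platform- or genome-wide universes give smaller
p-values for the same overlap). Rankings report raw p-values, ties broken
by larger overlap then name; an optional Benjamini–Hochberg column can be
added but does not affect ranking.

## Patient features

Each module contributes one feature: the per-patient mean expression of its
*effective* DEGs (module members present on the expression platform);
missing entries are excluded from that patient's mean. Clinical covariates
(numerically encoded) are joined on patient id; the default missing-data
policy is complete-case with a per-feature missingness report (median
imputation is available). All retained features are z-normalized across
patients with the sample (n−1) standard deviation; constant features are
dropped with a warning. Normalization is idempotent and shift/scale
invariant.

## Patient subgroups

Patients are clustered with PAM (k-medoids) on Euclidean dissimilarities of
the normalized features. PAM is implemented directly (greedy BUILD plus
best-improvement SWAP, ties to the lowest index, cost non-increasing) since
no installed library provides k-medoids; on small instances it matches the
exhaustive optimal medoid search. Robustness again comes from consensus:
`resamples` (100) subsamples of `subsample_fraction` (0.8) of the patients
drawn without replacement, consensus entry = co-clustering count /
co-sampling count (never co-sampled pairs get 0 with a warning — at 100
resamples of 80% the probability is negligible).

The group count scans k = 2..15 (2..8 in the default pipeline, matched to
the planted structure's scale) using the area under the consensus CDF
(AUCDFC) of the upper-triangle entries, computed as an exact step-function
integral on [0, 1]. The chosen k is the largest candidate satisfying all
of: relative gain Δ(k) = (A(k) − A(k−1))/A(k−1) (Δ(2) = A(2)) ≥
`delta_threshold` (0.03); consensus stability 1 − PAC ≥ `stability_floor`
(0.8); and stability within `stability_slack` (0.05) of the best stability
over the candidate range. The three conditions divide the work: the AUCDFC
gain alone decays too slowly to stop the scan (on pilot cohorts and blob
benchmarks over-split solutions keep adding 3–8% area per extra group), the
*relative* stability condition rejects over-splits whenever a crisper
partition exists, and the *absolute* floor prevents grouping structureless
data (which never produces crisp consensus), triggering the fallback to the
smallest candidate. Both feature regimes are clustered: all features, and
module features only.

## Survival evaluation

Kaplan–Meier product-limit tables per group, the g-sample log-rank test
(df = g − 1), Cox proportional-hazards fits and Harrell's concordance index
are provided through `lifelines` behind the module surface. Ties use
Efron's correction (the convention of the standard survival tooling; note
this makes "duplicate every subject" only approximately coefficient-
preserving, since duplication manufactures ties). Times are durations in
days, compared exactly for risk sets; events are 0 = alive/censored,
1 = dead. Cox fits reject constant and collinear covariate columns by name,
report per-covariate coefficients, SEs and two-sided Wald p-values with a
significance threshold of 0.05, and are run both pooled over all patients
and per patient group (groups with < 10 events are skipped with a warning).
The C-index scores risk (higher risk ⇒ earlier death) over comparable
pairs with 0.5 credit for ties.

## Synthetic cohorts

The generator plants the statistical structure every stage assumes, with
defaults fixed once as the study conditions:

* 200 tumours, 5 pathways, 1 driver and a 40-gene signature per pathway
  (signatures disjoint by default; `signature_overlap` shares a fraction
  with the neighbouring pathway to emulate shared drivers);
* each tumour belongs to one of 5 patient groups; its group pathway is
  fully active, other pathways activate at rate 0.05 with partial level
  0.5 — partial background activation keeps planted groups recoverable
  while still exercising the driver-frequency rules;
* the active pathway's driver is observed and assigned as the cause of
  each signature DEG with probability 0.7 (at least 5), posterior
  Uniform(0.7, 1.0); drivers of inactive pathways are also observed at
  rate 0.2 so the 25%-of-observed rule is non-trivial;
* 30 passenger SGAs are observed at rate 0.15 and, half the time, assigned
  1–3 arbitrary unassigned DEGs with posterior Uniform(0, 0.4) — removed
  by the posterior floor, and by standards 2–4 even if the floor is
  lowered;
* expression of a signature gene is 1.0 × activation + N(0, 1); 50 extra
  noise DEGs carry pure noise; `platform_dropout` removes a random gene
  fraction to exercise effective-DEG handling;
* survival is exponential with log-hazard Σ β_p · activation_p,
  β = linspace(0.9, −0.9) across pathways, baseline hazard 1/1000 per day
  (mean follow-up on the order of 2–3 years), with independent
  Uniform(0, c) censoring where c is solved by bisection so the expected
  censored fraction is 0.30;
* clinical covariates are age (group-shifted, sd 8 years) and two binary
  markers with mild group association.

What the generator does **not** emulate: realistic SGA mutation spectra or
copy-number segments, correlated expression noise between genes, pathway
cross-talk beyond signature overlap, non-exponential hazards, informative
censoring, and missing clinical data patterns. Passing tests therefore show
that each stage recovers the structure it is designed for under its own
assumptions — not that real cohorts satisfy those assumptions.

## Problem sizes and determinism

The default pipeline runs 100-run spectral consensus over k = 2..8 on a
~200-node network and 100-resample PAM consensus over k = 2..8 on 200
patients — a deliberate down-scaling of the procedure to a cohort size
where planted structure is still hard enough to be informative (passengers,
posterior noise, partial activations) but a full run takes seconds. Every
source of randomness flows from a single run seed through per-stage
`SeedSequence` spawns; reruns with the same seed are digest-identical, and
the run manifest records the config, stage seeds and SHA-256 digests of
all written artifacts.

## Known limitations

* Stability-based k selection assumes the candidate range brackets the true
  count and that instability appears promptly past it; hierarchically
  nested module systems can defeat the first-drop rule.
* The consensus-majority labels use average linkage on 1 − consensus; very
  unbalanced module sizes may need a different linkage.
* The Cox implementation inherits lifelines' behaviour for near-separable
  designs (large coefficients with warnings rather than hard failure).
* With `subsample_fraction` close to the minimum cluster fraction, PAM
  consensus entries become noisy; the warning on never-co-sampled pairs is
  the only guard.
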