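# oncomodules

Tumour genomes carry hundreds of somatic genome alterations (SGAs), only a
few of which drive disease, and the pathways they perturb differ from
patient to patient. Given tumour-specific causal assignments — tables in
which each differentially expressed gene (DEG) in a tumour is assigned
exactly one SGA as its cause, with a posterior probability — this package
reconstructs the downstream analysis that turns those assignments into
mechanism-oriented cancer subtypes:

1. **Filtering** — four standards reduce raw assignments to significant
   drivers and significant SGA→DEG relationships (posterior floor; ≥ 5
   DEGs per tumour-level driver call; driver in ≥ 30 tumours *and* ≥ 25%
   of tumours where the SGA is observed; relationship in ≥ 50 tumours *or*
   ≥ 20% of the SGA's driver tumours).
2. **Co-regulation network** — DEGs are nodes (kept if targeted in > 10%
   of tumours); the weight `W_ij` counts tumours in which DEGs i and j were
   co-assigned to a common SGA, with per-edge provenance of every
   (tumour, SGA, pair) instance.
3. **Spectral consensus modules** — weights become pseudo-distances
   `D_ij = 1/W_ij`, then affinities `A_ij = exp(−D_ij²/2σ²)`; the
   normalized-affinity embedding is clustered by seeded random-init
   k-means, 100 runs are pooled into a consensus matrix, and the module
   count is chosen from consensus stability (1 − PAC).
4. **Driver attribution** — an SGA producing > 10% of a module's internal
   co-regulation instances is a *dominant* SGA; gene-set overlaps are
   scored by upper-tail hypergeometric p-values.
5. **Patient features and subgroups** — each module's mean expression over
   its effective DEGs plus clinical covariates, z-normalized, clustered by
   PAM (k-medoids) consensus over subsampled resamples with the group
   count chosen by the area under the consensus CDF (AUCDFC).
6. **Survival** — Kaplan–Meier curves per group, the g-sample log-rank
   test, Cox proportional-hazards models with Wald tests, and Harrell's
   C-index.

Because the cohort data this kind of analysis consumes are
access-restricted, the package ships a first-class synthetic-cohort
generator that plants pathway structure (drivers, signatures, passengers,
expression effects, module-dependent hazards) and emits the six standard
input tables plus ground truth, so every stage is testable end to end.
See `docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (200 tumours, 5 planted pathways with one driver and a
40-gene signature each) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_filter_assignments.py
python analysis/03_network_and_modules.py
python analysis/04_annotate_modules.py
python analysis/05_patient_groups.py
python analysis/06_survival_analysis.py
```

Output of the module-discovery step:

```
network: 200 DEG nodes, 3900 edges, 92665 co-regulation instances
sigma = 0.04167 (median pseudo-distance); selected k = 5
 k  stability      pac
 2   0.517588 0.482412
 3   0.517588 0.482412
 4   0.758794 0.241206
 5   1.000000 0.000000
 6   0.991206 0.008794
 7   0.983668 0.016332
 8   0.981658 0.018342
module sizes: {1: 40, 2: 40, 3: 40, 4: 40, 5: 40}
adjusted Rand index vs planted signatures: 1.000
```

Stability (1 − PAC, the fraction of unambiguous consensus entries) climbs
to 1.0 at k = 5 — the planted pathway count — and degrades beyond it; the
recovered modules match the planted signatures exactly (ARI 1.0). The
attribution step then finds each module dominated by its planted driver
(100% of internal co-regulation), and the subgrouping/survival steps
report:

```
[all] 5 patient groups (sizes {1: 39, 2: 41, 3: 41, 4: 46, 5: 33}), ARI vs planted groups 0.951
[all] log-rank chi2 = 45.00 (df 4), p = 3.97e-09
Cox[all]: C-index 0.646 (200 patients, 145 events); significant: module_4 (0.408); module_5 (0.298)
```

i.e. the recovered patient groups separate survival strongly (the planted
hazards depend on pathway activation), and the Cox model flags the module
features carrying the largest planted hazard coefficients.

The same stages are scriptable through a CLI
(`oncomodules simulate|filter|network|modules|annotate|features|groups|survive|run`),
each command a thin wrapper over the library.

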