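# melnet

Co-expression modules, consensus directed gene networks, and survival-linked
network hubs from siRNA-perturbation expression data — with a synthetic-data
generator so the whole analysis is testable end to end without any downloads.

## The problem

Expression studies of tumours from patients are heterogeneous: gene
signatures for progression, metastasis and prognosis rarely replicate across
cohorts. An alternative is functional genomics in a cultured cancer cell
line: knock down a panel of transcription factors and signalling molecules
with siRNAs, measure genome-wide expression after each perturbation, and
read the regulatory structure out of the correlations the perturbations
induce. The analysis implemented here asks, in order:

1. Which genes form **co-expression modules** across the perturbed
   cultures? (Ward clustering on the dissimilarity 1−|ρ|, ρ = Spearman's
   rank correlation; clusters kept when size > 5, min pairwise |ρ| ≥ 0.4,
   median pairwise |ρ| ≥ 0.5.)
2. Which annotated **gene sets co-correlate in both** the cell-line data and
   tumour cohorts (valid in-vitro model, e.g. cell-cycle programmes) and
   which only in tumours (not modelled in vitro, e.g. immune response)?
   The statistic is the **correlated-pair fraction**: the proportion of a
   set's gene pairs with |ρ| ≥ 0.5 in a dataset.
3. Which genes sit **upstream** of the modules? A consensus directed network
   is assembled from many small subnetworks fitted to correlation
   neighbourhoods (greedy hill-climbing DAG search, Gaussian EBIC score);
   directed edges present in ≥ 20% of the subnetworks containing both
   endpoints are kept. Nodes with many downstream children are **hubs** —
   putative master regulators whose abundance summarises their module's
   activity.
4. Do hub levels in tumours **predict survival**? (Univariate Cox
   proportional-hazards screening per gene, −log2 p summaries with 4.32
   marking p = 0.05, Kaplan–Meier median splits.)
5. Can a handful of hubs **classify prognosis**? (Nearest shrunken centroid
   classifier over Cox-significant hubs, shrinkage chosen by
   cross-validation.)

The synthetic generator produces all required inputs with known ground
truth: hub-driven modules (shared / tumour-only / perturbation-only), a
designed siRNA experiment with batch structure and ~2.8-fold knockdowns, a
tumour cohort, and exponential survival whose log-hazard follows the
proliferation-like module's activity.

## Worked example

```bash
melnet run-all --outdir demo_run --seed 1
```

runs generate → preprocess → cluster → screen → network → survive →
classify and prints a report (abridged):

```
[generate] n_gene_sets=15, n_genes=100, n_modules=5, n_samples=60, n_tumours=50
[preprocess] median_fold_reduction=2.64..., n_genes_kept=80, ...
[cluster] k_requested=10, n_clustered_genes=24, n_retained_clusters=3
[screen] n_sets=15, n_shared_high=2, n_significant_enrichments=4, n_tumour_only_high=2
[network] n_conserved_hubs=1, n_edges=37, n_hubs=2, n_subnets=500
[classify] chosen_delta=2.3, cv_error=0.0625, n_candidates=1, n_selected_genes=1

correlated-pair fractions (|rho| >= threshold):
dataset_label  perturbation  tumour
MODULE_00             1.000   1.000     <- shared (cell-cycle-like)
MODULE_01             0.000   1.000     <- tumour-only (immune-like)
MODULE_02             1.000   0.000     <- perturbation-only
RANDOM_01             0.022   0.026     <- random sets stay near 0
```

Reading it: three of the ten dendrogram cuts survive the retention rules
(the modules active in the perturbation data); the pair-fraction screen
classifies two modules as shared-high and two as tumour-only-high, exactly
matching the generator's truth; the network stage finds the active hubs;
and the classifier, built on the surviving Cox-significant hub, reaches a
6% leave-out error against a ~47% permuted-label benchmark. Every artefact
(expression TSVs, GMT gene sets, survival CSV, edge list, hub table,
classifier model) lands in `demo_run/`, and `manifest.json` reproduces the
run bitwise: rerunning with the same config and seed gives identical files.

Single stages are available as subcommands (`melnet generate`,
`melnet network`, ... `melnet report`), and everything is importable from
Python (`melnet.coexpression`, `melnet.network`, `melnet.survival`, ...).

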