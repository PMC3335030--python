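# Methods

This note documents the models, estimators and numerical choices behind
`melnet`, and what the synthetic data can and cannot establish.

## Synthetic data model

Expression of gene *i* in sample *j* is

    x_ij = mu_i + w_i * a_m(i),j + b_batch(j),i + eps_ij

* `mu_i ~ Normal(7, 1)` — log2-scale baselines (linear abundances ~128).
* Each of `n_modules` disjoint modules (default 5, sizes 8–15 of 100 genes)
  has one hub with loading exactly 1 and children with |w| ~ Uniform(0.5,
  0.9), a random 20% sign-flipped so that clustering must use 1−|ρ|, not
  1−ρ.
* The module activity is **hub-anchored**: `a = z + eps_hub` with latent
  `z ~ Normal(0, 1)` per sample and `eps_hub ~ Normal(0, noise_sd)`. The
  hub's expression *is* `mu + a` (plus batch offset); children respond to
  the hub's realised deviation. Consequently children are conditionally
  independent given their hub — a directed star, which is the regulatory
  claim a network hub encodes. A purely latent driver would make all module
  members statistically exchangeable and hub identification impossible in
  principle, for any method.
* Module kinds cycle shared / tumour_only / perturbation_only. Activities
  vary only in the datasets where a kind is active; elsewhere the module
  transmits nothing (children are background noise there), though the hub
  transcript itself is still present and still knocked down when targeted.
* Batch offsets `b ~ Normal(0, 0.5)` per (batch, gene), three batches,
  mirroring a screen run in three experimental sittings. Noise
  `eps ~ Normal(0, 0.2)`.

**Knockdown.** The designed experiment has 45 knockdown samples (targets
cycling over the hubs) plus 15 controls. In a sample targeting hub *h*, the
hub's intrinsic level is clamped to `−log2(knockdown_fold)` — a
multiplication by 1/fold on the linear scale — and, for modules active in
vitro, the attenuation propagates to children through their loadings.
Latent activities are centred over control samples so a gene's control mean
equals its baseline exactly at zero noise. The default fold of 2.8 is the
median of the reference 45-target screen (all of whose printed fold/percent
pairs satisfy `percent = round(100·(1−1/fold))`, rounding half away from
zero; the table ships in `melnet.preprocess` as a fixed oracle).

**Tumour cohort and survival.** 50 tumours with shared and tumour-only
modules active. Survival times are exponential with
`log-hazard = Σ_m beta_m · a_m,j` over `baseline_hazard = 0.25`/year;
independent censoring marks each sample censored with probability 0.3 at a
Uniform(0, T) fraction of its event time. Only the first shared
(proliferation-like) module carries a nonzero `beta` (default 2.0,
calibrated so a typical default cohort supports the ~88% cross-validated
prognosis accuracy scale such screens report; beta = 1 leaves even the true
latent activity a weak classifier).

**Seeding.** One global seed; each stage derives its own sub-2^31 seed via
`SeedSequence([seed, stage_key])`. Identical seed + config reproduce every
artefact bitwise.

**What the generator does not emulate.** Probe-set-level artefacts (PM/MM,
RMA, cross-hybridisation), realistic microarray intensity distributions,
off-target siRNA effects, correlated module activities, non-proportional
hazards, and cohort composition effects. Tests passing on this data show
the estimators recover the structure they target under the stated model;
they do not certify performance on real arrays.

## Preprocessing

Per-gene, per-batch median centring on the log2 scale (equivalently
division on the linear scale; either choice is rank-preserving per gene, so
downstream Spearman statistics are unaffected). The noise-floor filter
keeps genes with median signal ≥ 1.5× a floor; with no spike-in control in
synthetic data the floor defaults to the 20th percentile of per-gene
medians. Knockdown efficacy is the linear-scale ratio (median of other
samples)/(own sample); per-sample estimates carry ±15% noise from
`noise_sd` alone, so round-trip checks compare the median across replicate
knockdowns.

## Clustering

Spearman correlations use average ranks (Pearson on ranks); constant genes
get ρ = 0 with a warning rather than NaN. Ward linkage is computed
"ward.D"-style on the raw 1−|ρ| dissimilarities: scipy's `linkage(...,
'ward')` applies the Lance–Williams recurrence to squared inputs, so it is
fed `sqrt(d)`; topology and cuts equal ward.D on `d`, with merge heights
returned square-rooted (monotone, so cutting is unaffected). The cut count
defaults to n_genes/10 (floor 10). Retained clusters satisfy size > 5,
min |ρ| ≥ 0.4, median |ρ| ≥ 0.5 — both rules on |ρ| since the dissimilarity
is built from |ρ| and clusters may mix positively and negatively correlated
genes. Cluster stability is plain bootstrap co-clustering (fraction of
sample-bootstrap trees in which ≥ 80% of a cluster co-occurs in one
cluster), a simpler substitute for multiscale-bootstrap AU values.

## Gene-set screen

Enrichment combines a strength criterion (hypergeometric upper tail,
reported as −log10 p, default threshold 1.3 ≡ p ≤ 0.05) with a seeded
permutation p ≤ 0.05, preserving the two-criterion structure of
web-tool-era screens whose Bayes-factor computation is not reproducible.
Under the exchangeable null the overlap of a random same-size query is
exactly hypergeometric, so the permutation draws overlap counts from
`rng.hypergeometric` directly. BH-FDR is reported alongside raw p. The
correlated-pair fraction drops unmeasured members (counting them) and
requires ≥ 2 measured members.

## Consensus network

Correlation neighbourhoods (a seed gene cycling through a permutation of
all genes, plus its top-|ρ| neighbours; 500 subnetworks of 15 nodes by
default) are each fitted by greedy hill climbing over add/delete/reverse
single-edge moves from the empty graph, acyclicity checked per move, at
most 3 parents per node, ridge 1e−8 on local regressions. The node score is
the **extended BIC** (gamma = 1): plain BIC admits an edge for any
|ρ| ≳ sqrt(ln n / n) (≈ 0.26 at n = 60), and because each seed gene yields
a deterministic neighbourhood, such chance edges recur in every subnetwork
containing the pair and survive any consensus frequency threshold. The
EBIC term `k·log(candidates)` is the standard small-sample correction for
exactly this many-candidate-edges regime and removes the chance-edge floor
without touching the consensus rule.

Edge frequency = (subnetworks containing the directed edge)/(subnetworks
containing both endpoints); edges with frequency ≥ 0.2 are retained. The
co-occurrence denominator keeps frequencies comparable across pairs with
different sampling coverage; dividing by all subnetworks instead is
selectable but caps every frequency near module_size/n_genes and fails at
the 0.2 threshold as gene count grows. An undirected mode pools both
directions. Hubs are nodes with ≥ `min_children` consensus children
(default 5, the desk-scale analogue of "≥ 50 of 54,000 probe sets"), ties
broken lexicographically.

Hub recovery is evaluated against hubs of modules **active in the training
data**: a tumour-only module has zero activity variance in the perturbation
dataset by construction, so its hub is statistically invisible there and no
method could recover it. Edge direction is reported but never asserted —
within a star's Markov-equivalence class one edge orientation is
undetermined, and directionality of such networks is experimentally
unvalidated in general.

Hub–child conservation counts children with |ρ(hub, child)| ≥ 0.4 in a
second dataset (≥ `min_conserved_children` ⇒ conserved). Parent-knockdown
consistency reports, per consensus edge with an siRNA-targeted parent, the
linear-scale ratio of the child's expression in the knockdown sample to its
median across all samples, signed so the value is always ≤ −1 or ≥ +1, and
pairs it with the parent–child ρ; positively correlated children trend
negative after parent knockdown.

## Survival

Univariate Cox per gene, continuous covariate, Breslow ties, Newton–Raphson
to |Δβ| < 1e−8 (steps clipped at 5 to survive monotone likelihoods;
non-convergent or |β| > 50 fits are flagged with p = 1). Wald two-sided p,
floored at 1e−300. Verified against R `survival::coxph(ties="breslow")` and
a grid-search partial-likelihood oracle. Summaries per functional category
report the −log2 p distribution with 4.32 (= −log2 0.05) as the
significance line and always include an all-genes baseline. Kaplan–Meier
median splits put ties in the low group and use the standard 1-df log-rank
test. No multiple-testing correction inside the screen; BH-FDR is an extra
column.

## Classifier

Nearest shrunken centroids: `d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0))` with
`m_k = sqrt(1/n_k − 1/n)` (the `+` convention is selectable; tests assert
internal consistency, not one convention), `s0` = median pooled sd,
soft-thresholding by Δ, class priors proportional (uniform selectable),
prediction by minimal standardized distance minus `2 log π_k`, ties to the
class listed first. Candidates are hubs with ≥ `min_children` children and
Cox p ≤ 0.05 (desk-scale analogue of ≥ 50 children and p ≤ 0.005); the
pipeline relaxes these stepwise with a logged warning rather than abort
when the short desk-scale hub list leaves the intersection empty. Prognosis
classes follow the event-before-2-years vs event-free-beyond-3-years
construction, samples in between excluded. Cross-validation is stratified
and seeded, leave-one-out for cohorts ≤ 30 (the scale at which such
classifiers are piloted), else 10-fold; the chosen Δ is the largest
attaining minimal CV error (fewest genes at equal error). Permuted-label
benchmarks quote the chosen classifier's CV error under permutation — which
approximates the majority-class rate — rather than re-minimising the grid
per permutation, which is optimistically biased; stochastic end-to-end
checks average over three replicate cohorts because a single ~30-sample
cohort's class balance dominates the single-draw estimate.

## Pipeline

Stages write plain-text artefacts (TSV/GMT/CSV/JSON) into a run directory;
the JSON manifest records the config snapshot, global and per-stage seeds,
outputs and summary metrics, and omits timings (logged instead), so reruns
with the same config and seed are bitwise identical. All analysis
thresholds (0.4, 0.5, 0.2, min children, p cut-offs, the 4.32 line) are
named config keys. Default problem sizes — 100 genes (50 for the network
evaluation), 5 modules, 60 perturbation samples, 50 tumours, 500
subnetworks of 15 — keep a full run under ten seconds on one CPU while
leaving every recovery statistic well away from its decision boundary.

## Known limitations

Greedy single-restart hill climbing finds local optima; consensus star
recovery can fragment near the `min_children` boundary (hence the
classifier stage's relaxation ladder). The consensus network is not
guaranteed acyclic (only each subnetwork is). Hub identifiability rests on
the hub-anchored generative assumption. The classifier's candidate filter
uses the same cohort's survival, as in the emulated design — a known
optimism for the reported CV error, which the permuted-label benchmark
quantifies but does not remove.
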