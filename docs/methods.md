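# Methods

## The model

`netstrat` stratifies a tumor cohort from somatic mutation calls alone.
The object being clustered is not the raw binary mutation profile — those
are too sparse and too disjoint across patients — but its steady-state
image under a restarting random walk on a protein-protein interaction
network.

**Propagation.** Let `W` be the column-normalized adjacency of the
network (weighted by interaction confidence unless `--binarize`), and let
`p⁽⁰⁾` put mass `1/m` on each of a patient's `m` mutated in-network genes.
The walk iterates

    p⁽ᵗ⁺¹⁾ = (1 − r) W p⁽ᵗ⁾ + r p⁽⁰⁾

until `‖p⁽ᵗ⁺¹⁾ − p⁽ᵗ⁾‖₁ < 1e-6`. Because `W` is column-stochastic on
non-isolated nodes and the graph is undirected, total mass is conserved,
so every smoothed profile is a probability distribution over network
genes. The L1 norm is used for the stopping rule to match that
interpretation. The fixed point solves
`p = r(I − (1−r)W)⁻¹ p⁽⁰⁾`, which the test suite uses as an independent
oracle (linear solve vs iteration, agreement within 1e-5 L∞ on 500-node
networks). The restart probability defaults to `r = 0.75`; larger values
localize mass near the seeds (`p^∞ → p⁽⁰⁾` as `r → 1`), smaller values
diffuse it further. Results downstream of `r` are treated as
configuration-sensitive, not as fixed truth. Patients whose entire
mutated set falls outside the network have no defined seed; the default
policy drops them with a record, `strict` mode raises.

The iteration is batched (all patients advance together) with one shared
stopping criterion — the maximum per-patient L1 change — so every row is
at least as converged as the tolerance demands. Dense matrix products are
used up to 5000 nodes, sparse above; the contract is the result, not the
mechanism.

**Feature filter.** Genes are ranked by the sample variance (n−1
denominator) of their smoothed scores across patients and the top 500
kept. Coefficient of variation is available as an alternative ranking
(`variability="coefficient_of_variation"`); the two appear
interchangeably in the source literature for this pipeline and the
discrepancy is surfaced as configuration rather than silently resolved.
Selection happens once, before centering, and is not repeated per k.

**Centering and the nonnegative orthant.** The retained matrix is
median-centered per gene, which necessarily produces negative entries,
while the factorization requires `A ≥ 0`. The default repair is a global
shift by `|min|` (rank- and distance-preserving); clamping negatives to
zero is available. After the repair the matrix is rescaled to unit
root-mean-square entry. This last step matters: the factorization
objective balances a data-misfit term that scales with `‖A‖²` against a
graph penalty `λ·Tr(VᵀLV)` that does not, so the effective strength of a
fixed `λ` depends on the raw data scale. At the natural scale of smoothed
profiles (entries ~1e-2) the penalty at `λ = 150` dominates, the
multiplicative updates collapse factor components, and cluster recovery
fails; at unit RMS the same `λ` acts as the mild smoother the method
intends. Reference implementations of graph-regularized NMF normalize
their input for the same reason. The transform (`center`, `nonneg_fix`,
`scale`, shift and RMS values) is recorded in the stage manifest.

**Graph-regularized NMF.** With `A` (genes × patients), the factorization

    min_{U,V ≥ 0}  ‖A − UVᵀ‖²_F + λ·Tr(VᵀLV)

is solved by the standard multiplicative updates

    U ← U ∘ (AV) / (UVᵀV)
    V ← V ∘ (AᵀU + λSV) / (VUᵀU + λDV)

where `S` is a 0/1 5-nearest-neighbor graph over patients (Euclidean
distance on columns of `A`, tie-inclusive at the k-th distance,
symmetrized by union), `D` its degree matrix and `L = D − S`. Denominators
are floored at 1e-12 — a numerical guard that does not move fixed points.
`U, V` initialize entrywise uniform(0,1) from the run seed; identical
config + seed reproduces results bitwise. The updates never increase the
objective (asserted within 1e-9 relative slack), reduce exactly to plain
NMF at `λ = 0` (pinned against an independent update loop to 1e-10 over
20 steps), and the reported objective trace re-evaluates from the
returned factors to 1e-8 relative. Orientation follows the standard
convention: `V` (patients × k) carries cluster structure, labels are the
per-row argmax of `V` with ties to the lowest index.

**Consensus and model selection.** For each candidate `k` the
factorization is restarted `n_runs` times (default 100) from seeds
`base_seed + run`; runs differ *only* by initialization. The consensus
matrix holds co-clustering frequencies; final labels cut the
average-linkage dendrogram of `1 − consensus` at `k`, making them a
deterministic function of the consensus matrix rather than of any single
run. Model selection takes the `k` maximizing the cophenetic correlation
between the consensus distances and the dendrogram's cophenetic
distances; ties go to the smaller `k`. When the dendrogram reproduces the
distances exactly (perfect 0/1 block consensus, or a constant distance
matrix) the coefficient is exactly 1.0, with a degenerate flag in the
constant case. A run that fails is retried once with a shifted seed and
then excluded; more than 10% exclusions abort the consensus.

**Core samples.** Silhouette widths are computed on the consensus
distance (`d = 1 − consensus`): `s(i) = (b − a)/max(a, b)` with
singleton-cluster members assigned 0. The core set keeps widths strictly
above 0.20. Feature-space distances are available behind a flag-free
path (compute widths on any distance you like by calling
`silhouette_widths` with your own matrix); the consensus distance is the
default because the core set should reflect clustering stability, not
geometry.

**Classifier.** A multinomial logistic model under the elastic-net
penalty `λ[(1−α)/2·‖β‖₂² + α·‖β‖₁]` (glmnet parameterization) is fit to
the core samples' top-N smoothed features, standardized to zero mean /
unit variance on the training portion of each fit. The optimization is
delegated to scikit-learn's saga solver via `C = 1/(n·λ)`,
`l1_ratio = α`; the objective, the (α, λ) grid and the leave-one-out
loop are implemented here. The jackknife holds out each sample once per
grid point; the winning grid point minimizes the error with ties broken
toward larger λ then smaller α (parsimony). The leave-one-out loop
warm-starts each fold from the previous fold's coefficients — consecutive
folds differ by one sample and the per-fold optimum does not depend on
the starting point, so this changes iteration counts, not results (the
loop is pinned against a cold-start re-implementation in the tests).
Per-subtype biomarkers are the genes with a nonzero coefficient in that
subtype's row; for binary problems the single contrast row returned by
the solver is expanded to symmetric per-class rows.

Leave-one-out error on label-free data is *pessimistic*, not 0.5:
removing a sample of one class makes the other class the training
majority, so a shrunk classifier systematically votes against the
held-out sample. The null-model test asserts "never better than chance"
rather than a band around 0.5 for this reason.

**Clinical battery.** Ordinal grade, positive-node count and the
PSA-like marker get tie-corrected Kruskal-Wallis tests; stage and nodal
categoricals get Pearson chi-square with the Yates continuity correction
applied exactly and only to 2×2 tables — that convention is pinned by the
four published contingency p-values the tests reproduce to 3 significant
figures (the 2×2 values match only with the correction, the 3×2 value
only without). Missing values are excluded variable by variable; all
tests are two-sided; no multiple-testing correction is applied across the
battery. Survival uses the product-limit estimator and the log-rank test
(lifelines); a battery with no events anywhere returns a degenerate flag
and p = 1 instead of failing.

## The synthetic cohort generator

The generator emulates what the pipeline actually relies on:

* **Network** — planted-partition topology: `n_genes` (default 1000) in
  `n_modules` (default 10) modules, edge probability 0.15 within and
  0.002 across modules, edge scores uniform on (0.7, 1.0] so the
  high-confidence threshold keeps every edge unless a test overrides
  scores. Planted-partition rather than scale-free, because the smoothing
  mechanism being tested is "drivers of one subtype share a
  neighborhood", which module structure controls directly.
* **Cohort** — default 300 patients in 3 balanced subtypes. Each
  subtype's 5 driver genes are drawn inside its own module and mutate
  independently with probability 0.8; every gene mutates with background
  probability 0.002; an 8% hypermutator fraction has the background rate
  multiplied by 25. Patients with zero mutations are redrawn (the walk
  needs a seed). These sizes give ~4 driver + ~2 background mutations for
  a typical patient and ~50 for a hypermutator, so background hits
  outnumber driver hits for most of the matrix and per-patient burden
  spans more than an order of magnitude — the regime in which consensus
  runs at a wrong `k` genuinely disagree with each other. A noiseless
  cohort would make *every* `k` look perfectly stable and the cophenetic
  criterion vacuous.
* **Clinical table** — per-subtype categorical distributions over a
  6–10 ordinal grade, a binary nodal status (plus a Poisson positive-node
  count), a log-normal PSA-like marker, and exponential survival with
  censoring. The default effect spec shifts grade, nodal status and the
  marker by subtype while survival is identical across subtypes,
  mirroring a cohort whose follow-up is too short for survival
  differences. `ClinicalEffectSpec.null(k)` gives identical distributions
  for calibration tests.

What the generator does **not** emulate: trinucleotide mutation spectra,
copy number, rearrangements, variant classes with differential effect,
gene length confounding, or network ascertainment bias. Passing tests
demonstrate that the pipeline recovers structure *of the planted kind*;
they say nothing about whether real cohorts contain such structure.

## Problem sizes used by the tests and the acceptance script

The multi-seed experiments run the reference conditions (300 patients,
1000 genes) with consensus over `k ∈ {2,…,5}` at 20 restarts per k, and a
classifier grid of `α = 1.0`, `λ ∈ {0.05, 0.01}` at leave-one-out
tolerance 1e-3 — sizes chosen so a five-seed experiment completes in
minutes while leaving every qualitative property (k selection, recovery,
accuracy) intact. The pipeline defaults remain the full-size settings
(k 2–9, 100 restarts, 10 × 50 tuning grid).

## Numerical choices and degenerate inputs

* Strict inequalities where the method says "greater than": interaction
  score > 0.7 (a 0-1000-scale score of exactly 700 is dropped),
  silhouette width > 0.20, recurrent-gene fraction > 5%.
* Duplicate/reversed network edges keep the maximum score; self-loops are
  dropped; isolated nodes keep all-zero columns in `W` and are reported.
* Variance ties in gene ranking break by gene symbol ascending; argmax
  ties in cluster assignment break to the lowest index; tuning ties break
  to larger λ then smaller α; cophenetic ties break to smaller k.
* Percentages round half-up to two decimals, matching the printed-table
  style the cohort-arithmetic checks compare against.
* A constant Kruskal-Wallis input returns statistic 0, p = 1, degenerate
  flag; a single-cluster silhouette raises; a no-event log-rank returns
  p = 1 with a degenerate flag.

## Known limitations

* The cophenetic criterion prefers *stable* clusterings, which on clean
  data can tie between the true k and a coarser one; noise in the cohort
  is what breaks the tie. Interpret selected k on near-noiseless data
  with care.
* λ = 150 is the conventional default for this pipeline family, made
  scale-free here by the unit-RMS input convention; it is not tuned per
  dataset.
* Gene identity is the bare trimmed symbol, case-sensitive; no alias
  resolution is attempted — symbol mismatches between a mutation table
  and a network are reported, not repaired.
* The battery tests each clinical variable marginally; no multivariate
  survival modeling.
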