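# netstrat

Network-based stratification of tumor cohorts from somatic mutation
profiles.

Somatic point mutations are a poor clustering substrate on their own: a
typical exome carries well under 100 mutated genes, two patients of the
same biological subtype often share not a single mutated gene, and
per-patient burden spans orders of magnitude. `netstrat` implements the
standard remedy: project each patient's binary mutation profile onto a
protein-protein interaction network and smooth it there, so that patients
whose mutations hit *interacting* genes become comparable, then cluster the
smoothed profiles.

The pipeline, for a cohort of patients and a scored interaction network:

1. **Binary coding** — gene *g* gets a 1 for a patient iff the patient has
   ≥ 1 somatic mutation in *g*.
2. **Network smoothing** — each profile seeds a random walk with restart,
   `p⁽ᵗ⁺¹⁾ = (1 − r) W p⁽ᵗ⁾ + r p⁽⁰⁾`, with `W` the column-normalized
   adjacency, restart probability `r = 0.75`, iterated until the L1 change
   is below 1e-6.
3. **Feature filter** — genes ranked by variance of the smoothed scores
   across patients; top 500 kept; median-centered per gene and shifted back
   to the nonnegative orthant.
4. **Graph-regularized NMF** — `min_{U,V≥0} ‖A − UVᵀ‖²_F + λ·Tr(VᵀLV)`
   with `λ = 150` and `L` the Laplacian of a 5-nearest-neighbor patient
   graph, solved by multiplicative updates.
5. **Consensus clustering** — the factorization is restarted from many
   random initializations per candidate `k ∈ {2,…,9}`; the consensus matrix
   records co-clustering frequencies; the `k` with the highest cophenetic
   correlation coefficient wins; final labels cut the consensus dendrogram.
6. **Core samples** — patients with silhouette width > 0.20 on the
   consensus distance form the core set.
7. **Subtype classifier** — a multinomial elastic net
   (`λ[(1−α)/2‖β‖² + α‖β‖₁]`), tuned by the jackknife (leave-one-out) over
   an (α, λ) grid; genes with nonzero coefficients are per-subtype
   biomarkers.
8. **Clinical battery** — Kruskal-Wallis for ordinal/continuous
   characteristics, chi-square (Yates only for 2×2) for categorical ones,
   Kaplan-Meier + log-rank for survival.

A synthetic-data module generates cohorts with the structure the pipeline
assumes — a modular scored network, planted subtypes with module-confined
driver genes, sparse background mutations, hypermutator outliers, and
clinical covariates that shift by subtype — so the whole pipeline is
testable without any download.

## Worked example

```sh
python examples/stratify.py
```

```
cophenetic coefficient by k:
  k=2: 0.9488
  k=3: 0.9975 <- selected
  k=4: 0.9964
  k=5: 0.9949
ARI vs planted subtypes: 1.000
core samples (silhouette > 0.20): 119 of 120
jackknife accuracy on core samples: 0.933
```

The cophenetic coefficient peaks at the planted number of subtypes (3), the
recovered labels match the planted partition exactly (adjusted Rand index
1.0), one noisy patient falls below the core-sample silhouette threshold,
and the tuned elastic net re-predicts the subtype of held-out core patients
with 93% accuracy. The other example scripts demonstrate cohort
simulation (`simulate_cohort.py`), network smoothing (`smooth_profiles.py`),
the clinical battery (`clinical_associations.py`) and biomarker extraction
(`classify_subtypes.py`).

A thin CLI wraps the same calls:

```sh
netstrat simulate --seed 1 --out cohort/        # write MAF + edges + clinical
netstrat run --config pipeline.yaml --out out/  # full pipeline
netstrat stats --table "145,40;107,13" --yates  # spot-check a chi-square
netstrat report --maf cohort/mutations.maf      # burden/recurrence summary
```

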