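# oanet — network-based cytokine-driver inference for knee osteoarthritis

Traumatic knee injury accelerates osteoarthritis far more in aged joints
than in young ones, and the transcriptomic stress response that drives this
difference is not explained by any single differential-expression list.
`oanet` implements, as a tested and reusable pipeline, the chain of analyses
needed to go from age-stratified injury time-course data to a candidate
cytokine driver and compounds that might reverse it:

1. **Age-specific response selection** — genes significantly regulated
   (FDR < 0.05) at both week 1 and week 2 after injury in aged but at
   neither timepoint in young animals, with PCA trajectory summaries.
2. **Random-walk-with-restart (RWR) propagation** — on a weighted
   tissue-specific gene network, iterating `p ← (1−r)·M·p + r·e` from a
   seeded receptor (restart r = 0.7) until the L1 change falls below 1e−10;
   nodes with strictly positive affinity are "pseudo-activated".
3. **Cytokine activity inference** — ridge regression
   `ẑ = (SᵀS + λI)⁻¹ Sᵀy` of a log2FC response profile y on a cytokine
   signature matrix S, with z-scores from a gene-label permutation null.
4. **Single-sample GSEA** — weighted running-sum enrichment
   (weight |score|^α, α = 0.75) of a gene set in a ranked profile, with
   leading-edge extraction at the running-sum extremum.
5. **DerSimonian–Laird meta-analysis** — Hedges-corrected standardized mean
   differences `d = (m_t − m_c)/s_p` pooled with random-effects weights
   `1/(v_i + τ²)`, τ² by the method of moments, plus Q and I².
6. **2×2 enrichment statistics** — Fisher's exact test (probability-mass
   two-sided rule) and single-predictor binary logistic regression over an
   explicit gene universe.
7. **Co-expression modules** — filterByExpr-style count filtering, unsigned
   `|cor|^β` adjacency, topological overlap (TOM), and average-linkage
   clustering with a minimum module size of 30 and deep split 2.
8. **Connectivity-map tau scoring** — weighted KS connectivity of an
   upregulated query against perturbation rank profiles, sign-stratified
   normalization, and the signed tau percentile; tau < −90 shortlists
   candidate signature reversers.

A synthetic-data module (`oanet.simulate`) generates every input with
planted ground truth — planted age-specific genes, a modular network wired
to a receptor, known cytokine activities, a known pooled effect size,
blocked count matrices, and a planted signature-reversing perturbation — so
the whole pipeline is exercisable and testable without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each prints what it found and writes its tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_select_stress_genes.py
python analysis/04_network_propagation.py
```

Output of the selection and propagation steps (seed 1):

```
200 age-specific response genes selected -> results/stress_up.gmt
recall vs planted truth: 1.000; precision: 1.000
PC1 explains 94.9% of trajectory variance

RWR converged in 16 iterations; 40 pseudo-activated genes
driver ranking (seed, odds ratio, p):
    seed  n_activated  overlap  odds_ratio            p
RECEPTOR           40       30   33.000000 1.172846e-15
 G000115           39        6    0.465241 1.381425e-01
```

The selection stage recovers exactly the 200 planted age-specific genes;
the planted receptor's pseudo-activated neighbourhood is 33-fold enriched
for those genes, while decoy seeds score at or below chance — the pattern
the driver-inference design is built to detect. The remaining scripts show
the planted cytokine topping the activity z-ranking, the stiffness gene set
enriched only in the aged week-1/week-2 profiles, perfect recovery of the
three planted co-expression modules, and the planted reverser compound at
tau = −100.

Every stage is also exposed as a CLI subcommand
(`oanet simulate|stress|meta|propagate|cytokines|ssgsea|enrich|coexpr|cmap|run-all`).

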