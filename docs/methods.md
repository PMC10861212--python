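# Methods

This note documents the models and procedures implemented in `oanet`, the
parameter defaults and why they were chosen, what the synthetic-data
generators emulate, and the numerical conventions that matter for
reproducing results.

## Age-specific response selection (`oanet.stress`)

A gene belongs to the age-specific trauma response when it is significantly
regulated (FDR below threshold, default 0.05) in the stated direction at
*every* required timepoint (default W1 and W2) in the target contrast
(aged), and is excluded when significant at *any* required timepoint in the
exclusion contrast (young). The any-timepoint exclusion is the reading
consistent with taking a four-list Venn (young-W1, young-W2, aged-W1,
aged-W2) and keeping the aged-only intersection; `exclusion="all"` gives
the laxer alternative. Direction is taken from the sign of log2FC at each
timepoint independently, so a gene up at W1 and down at W2 is never
selected. Trajectory PCA centres (does not scale) the condition × gene
log2FC matrix and fixes component signs by making each loading vector's
largest-magnitude entry positive.

## Random walk with restart (`oanet.netprop`)

The transition operator is column-stochastic, `M[u,v] = w(u,v)/deg_w(v)`,
with isolated nodes self-absorbing. The walk iterates
`p ← (1−r)Mp + r·e` (e uniform over seeds) until the L1 change is below
1e−10, with a 10,000-iteration guard. The restart probability defaults to
0.7, the documented default of the reference multiplex-RWR implementation
this stage mirrors; it is exposed as a parameter. Edge confidences are used
as weights directly (a binarized walk is one flag away). Unreachable nodes
receive *exactly* zero affinity — power iteration from a seed-restricted
start never moves mass across components — so the pseudo-activation rule
"affinity > 0" needs no epsilon. This rule carries information only on
networks that are not fully connected, which is the realistic regime:
experimentally supported interaction networks are sparse and fragmented.
Community detection uses greedy weighted-modularity agglomeration with
deterministic ordering; the original tissue-network tool's proprietary
clustering is not published in reproducible detail, and greedy modularity
is the standard transparent stand-in.

## Cytokine activity inference (`oanet.cytokines`)

The response profile y (per-gene log2FC) is modelled as y = Sz + ε for a
gene × cytokine signature matrix S. After intersecting genes and centring
both sides, the ridge estimate is `ẑ = (SᵀS + λI)⁻¹Sᵀy`. λ defaults to
5-fold cross-validation over {10², 10³, 10⁴}, the penalty family published
for signature-based cytokine regression; a fixed λ can be supplied.
Significance comes from permuting y over the shared gene index (preserving
the correlation structure of S) with a mandatory seed, n_perm = 1000 by
default; per-cytokine z = (ẑ − mean_null)/sd_null and two-sided empirical
p with the +1 correction. A "cytokine elevated in aged" call requires a
positive aged coefficient exceeding the young coefficient at every compared
timepoint. A source-tissue filter keeps candidates whose expressing-cell
fraction exceeds 1% in the source tissue and stays below 1% in the target,
the rule used to separate synovium-derived from chondrocyte-intrinsic
cytokines.

## Single-sample GSEA (`oanet.ssgsea`)

For a descending-ranked profile and gene set S, the in-set cumulative
fraction weights members by |score|^α (α default 0.75, the single-sample
convention) while the out-of-set fraction is unweighted; the running
difference yields two statistics: the integral (sum over positions — the
reported single-sample score) and the maximum deviation (the classic KS
statistic, which defines the leading edge: members at or before a positive
extremum, after a negative one). Ties in scores break by ascending gene
symbol; an exact positive/negative extremum magnitude tie resolves to the
positive deviation. The permutation null redraws the member positions
uniformly; NES divides the observed integral by the mean |null| of matching
sign. The shipped 11-gene cartilage-stiffness set (BMP2, CHAD, COL3A1,
COL6A1, COL9A1, COL11A1, EGFR, MATN2, MATN3, MATN4, PRG4 — genes whose
knockout/knockdown lowers cartilage ECM stiffness) is the default query of
the stiffness stage.

## Meta-analysis (`oanet.meta`)

SMD `d = (m_t − m_c)/s_p` with the pooled SD over both arms; the Hedges
small-sample correction `J = 1 − 3/(4·dof − 1)` is on by default (the
convention of the standard systematic-review software), with variance
`(n_t+n_c)/(n_t n_c) + d²/(2(n_t+n_c))`. DerSimonian–Laird pooling:
fixed-effect weights give Cochran's Q; `τ² = max(0, (Q − (k−1))/c)` with
`c = Σw − Σw²/Σw`; random-effects weights `1/(v_i+τ²)`; normal 95% CI (no
Knapp–Hartung adjustment); `I² = max(0, (Q−(k−1))/Q)·100`. Semiquantitative
histology scores are rescaled to 0–100 from their instrument range before
effect computation. Averaging effects across timepoints within one age
group uses the simple mean of d and of the variances — a documented
simplification that ignores between-timepoint correlation, which the
source summaries do not report.

## Enrichment statistics (`oanet.enrich`)

The 2×2 table is always built over an explicit, caller-supplied gene
universe; odds ratios are meaningless without one, so it is never inferred.
Fisher's two-sided p uses the probability-mass rule (sum of hypergeometric
outcomes at most as probable as the observed table, the R convention); the
odds ratio is the sample OR ad/bc with the Woolf logit CI when all cells
are positive. The logistic route fits a single-predictor binary logit by
Newton's method; on a saturated 2×2 collapse exp(β₁) equals the sample OR,
and perfect separation (a zero cell) is rejected with a pointer to the
exact test. No multiple-testing correction is applied inside the module —
the analyses it supports test a-priori hypotheses — but a
Benjamini–Hochberg helper is provided.

## Co-expression modules (`oanet.coexpr`)

Counts are filtered by the documented count-based rule: keep genes whose
CPM (cutoff `min_count/median(lib)·1e6`, min_count = 10) is reached in at
least as many samples as the smallest group — shrunk to `10 + (n−10)·0.7`
above ten — with total count ≥ 15. Adjacency is unsigned `|cor|^β`
(Pearson); β is chosen as the smallest power whose connectivity
distribution fits scale-free topology at R² ≥ 0.8, falling back to the
argmax with a warning. TOM follows
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` with unit diagonal.
Modules come from average-linkage clustering of 1−TOM with a *static* cut
at the fraction `0.95 − 0.05·deep_split` of the merge-height range
(deep split 2 ⇒ 0.85), followed by a deterministic cohesion trim: members
whose mean within-cluster dissimilarity exceeds the cluster median by more
than 3 MADs are detached. This two-step static cut is the declared
simplification of the dynamic hybrid tree cut, whose many interacting
heuristics are out of proportion to its role here; the trim plays the role
of the hybrid method's core/PAM stage and is what keeps unrelated
background genes out of modules. Clusters below the minimum size (default
30) are relabelled module 0 (unassigned). Module preservation statistics
are out of scope.

## Connectivity-map scoring (`oanet.cmap`)

The query's connectivity to a perturbation profile is the weighted KS
enrichment (α = 1, maximum-deviation form) of the query set in the
profile's descending ranking — shared with the ssGSEA implementation. With
only an up-regulated query the score is ES_up (the study design submits
up-gene lists only); the two-sided (ES_up − ES_down)/2 form exists behind a
flag and zeroes when both components share a sign. Scores are normalized
within (cell line, sign) groups by the mean |ES|, and tau is the signed
percentile of |NCS| among same-sign reference scores (the rest of the
library, self-excluded). The shortlist keeps perturbations whose mean tau
across cell lines is below −90, the recommended reverser threshold. Note
that within a self-referenced library, tau is a percentile by construction,
so ~10% of same-sign perturbations fall below −90; the planted-reverser
test therefore checks that the planted compound is the *most* negative,
not merely shortlisted.

## Synthetic data (`oanet.simulate`)

All generators are deterministic functions of their seed and write the same
on-disk formats the pipeline reads.

- **DE time course**: two contrasts (young/aged) × four timepoints
  (D1, W1, W2, W6). Planted genes get log2FC centred on 2.0 at W1 and W2 in
  aged only; observed estimates carry standard error `noise_sd/√n_rep`
  with n_rep = 4 animals per group (the typical design of the murine injury
  studies this emulates), so null p-values are Uniform(0,1) and planted
  genes are reliably significant — which the selection contract requires.
  FDR is Benjamini–Hochberg within each contrast × timepoint, the field
  default where the source analyses leave the procedure unstated.
- **Network**: planted-partition graph, weights Uniform(0.1, 1.0), a
  reserved RECEPTOR node wired into one module with ≥ 3 edges. The driver
  benchmark uses disconnected modules (p_out = 0), mirroring the fragmented
  topology of curated interaction networks that makes strict-positivity
  pseudo-activation informative.
- **Signature response**: S sparse (10% nonzero) ± entries, columns
  L2-normalized; y = Sz + N(0, noise_sd²). Because columns are unit-norm
  and gene noise has unit SD, a planted activity of magnitude a yields a
  detection z-score ≈ a; the recovery condition plants |a| = 6 ("strong
  activation", comfortably above the ≈2.5-SD maximum of 37 null scores)
  with per-gene effects of realistic log2FC size (≈ 0.4).
- **Meta studies**: per-study true effects N(true_smd, τ²), unit-variance
  arms, observed means/SDs with genuine sampling error.
- **Expression modules**: one latent factor per module, gene loading
  √within_cor, log-normal rates (baseline ≈ 250 counts, so Poisson noise
  does not erode the nominal correlation — `within_cor` is meant to be the
  realized correlation), library sizes ×[0.5, 2]. The three-module recovery
  condition uses 38 samples, the size of the archived cartilage RNA-Seq
  cohort this stage emulates.
- **Perturbation library**: random permutations of symmetric centred rank
  scores; the planted reverser places every query gene at the bottom ranks.

What synthetic recovery does and does not show: the generators plant
exactly the signal structure each stage is designed to detect, with
Gaussian/Poisson noise and none of the confounders of real data (batch
effects, correlated nulls, annotation error, compositional effects,
negative-binomial overdispersion). Passing recovery tests demonstrates that
the implementations are correct and sensitive at realistic signal-to-noise
ratios; it does not certify performance on any particular real dataset.

## Numerical conventions and degenerate inputs

- RWR convergence by L1 norm at 1e−10; the dense closed-form solve
  `r(I−(1−r)M)⁻¹e` is the test oracle, never the production path.
- ssGSEA extremum ties (positive vs negative deviation of equal magnitude)
  resolve positive, with a 1e−12 tolerance against float noise.
- Fisher degenerate tables: OR = ∞ when bc = 0 with ad > 0, 0 when ad = 0
  with bc > 0, NaN when both products vanish; p is always defined.
- All-equal dissimilarity in module cutting yields a single module (the
  documented tie behaviour); fewer genes than the minimum module size
  yields all-unassigned with a warning.
- Permutation p-values use the +1-corrected empirical estimator and are
  therefore never exactly zero.
- Per-stage seeds derive from the global seed by a stable SHA-256 hash of
  the stage name, kept below 2³¹, so adding a stage never perturbs another
  stage's randomness.

## Problem sizes used in validation

The acceptance script and test suite validate at sizes chosen to keep the
full run in the minutes range while preserving the regime each claim is
about: 50 random graphs up to 200 nodes for RWR; exhaustive KS enumeration
to N = 20, k = 4; exhaustive Fisher tables to n = 22 plus a seeded sample
to n = 40; 200 meta-analysis replicates at k = 20 studies; 50 seeds of the
2000-gene, 40-cytokine recovery design; one 180-gene three-module
co-expression recovery; 20 seeds of the 200-node driver benchmark.
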