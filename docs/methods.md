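# Methods

This note documents the statistical model behind `polyliab`, the defaults
and the reasoning for them, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Liability-threshold calculus

Liability is modelled as N(0, 1) in the population with diagnosis iff
liability > t = Φ⁻¹(1 − K). Derived quantities (all in liability SD):

- mean liability of affected subjects: φ(t)/K;
- mean liability of unaffected subjects: −φ(t)/(1 − K);
- carrier shift δ for a class with ρ-fold excess risk:
  δ = t − Φ⁻¹(1 − K_c).

Two parametrizations of "ρ-fold" are implemented and always named
explicitly, because they disagree materially at large ρ:

- `risk_ratio`: K_c = ρK (at K = 0.015, ρ = 15 → δ = 1.4147);
- `odds_ratio`: K_c = ρΩ/(1 + ρΩ), Ω = K/(1 − K) (→ δ = 1.2772).

The default for reporting is `odds_ratio`. Similarly, "the point midway
between the group means" has two readings that differ because the group
means are not symmetric about zero: the arithmetic midpoint
(a + u)/2 = 1.243 and the half-distance (a − u)/2 = 1.282 at K = 0.015.
Reports emit both, labelled. `additivity_diagnostics` additionally
expresses δ and any observed carrier mean as a *position* on the
[unaffected-mean, affected-mean] interval (0 = unaffected mean,
1 = affected mean, 0.5 = exactly between), which is parametrization-free
and is the recommended way to compare analytic and observed values.

Group means are validated against numerical integration of the truncated
normal to 1e−6 over K ∈ {0.5, 0.1, 0.015, 0.001}.

## Synthetic cohorts

`simdata` generates the statistical structure the analysis assumes, with
ground truth for recovery testing. One global seed drives named
substreams (architecture, cohort sampling, population sampling, GWAS
sampling, PDV records), so outputs are byte-identical across runs and
the *trait* — ancestral frequencies, cluster frequencies, causal variant
set, causal effects — is shared by every sample drawn under the same
seed. An independent discovery GWAS (`simulate_gwas_stats`) therefore
measures the same trait as the analysis cohort while sharing no subjects.

Defaults and rationale:

- **k = 4 clusters, F = 0.01** (Balding–Nichols): continental-scale
  European substructure; cluster frequencies are Beta(p(1−F)/F,
  (1−p)(1−F)/F) around ancestral frequencies uniform on [0.05, 0.95].
- **h² = 0.70**: the fixed common-variant heritability used throughout;
  it is an input, never estimated.
- **prevalence K = 0.015**, threshold t = 2.170.
- **m_causal = m/10 by default**, effects drawn N(0, h²/m_causal) on the
  standardized-genotype scale and rescaled so Σβ² = h² exactly. The
  rescaling pins the liability variance at 1, so realized prevalence and
  carrier odds match their targets up to sampling noise instead of
  drifting with the effect draw.
- **pdv_rate = 0.008**: chosen so that roughly 10% of ascertained cases
  are carriers, matching the composition of the cohorts this style of
  analysis is applied to.
- **pdv_shift**: defaults to δ = carrier_shift(K, 15, odds_ratio) =
  1.277, so carrier status realizes a ~15-fold excess of disease odds;
  validated by simulation on ≥ 2 × 10⁵ unascertained subjects.
- **Ascertainment**: rejection sampling for cases (hard cap 10⁷ draws);
  matched controls are drawn to the cases' exact per-cluster composition;
  the pool controls are unaffected subjects drawn irrespective of
  matching and are the only source of allele-frequency estimates.

Known deviation from the idealized model: the polygenic component is a
finite sum of standardized binomial dosages, which has positive excess
kurtosis. At t ≈ 2.17 this inflates realized prevalence by ~5–10%
relative to K (e.g. ~0.0164 vs 0.015 at 500 causal variants). Tests
therefore check prevalence strictly only in the h² = 0 regime (exactly
normal liability) and with a relative tolerance in the genotypic regime.
PDV variance is deliberately excluded from the h² bookkeeping
(environmental variance is 1 − h²), so carrier liability variance
slightly exceeds 1; carriers are rare, so the population-level effect is
negligible.

What the generator does **not** emulate: linkage disequilibrium beyond
structure-induced correlation, genotyping error, missingness (injectable
by hand), sex chromosomes, assortative mating, cryptic relatedness, and
realistic site-frequency spectra. Passing recovery tests therefore show
the pipeline's statistical machinery is correct under its own model
assumptions — not that real-cohort effect sizes would be reproduced. In
particular the synthetic PRS is far more informative than a real
external-GWAS PRS, because the discovery GWAS measures the identical
trait with a sparse causal architecture in the identical population.

## Ancestry and matching

Variants are LD-pruned with a greedy moving-window filter (defaults:
50-variant windows, step 5, r² < 0.64); within a window the
later-positioned member of an offending pair is removed, ties broken by
variant id. Ancestry eigenvectors are the top d = 3 eigenvectors of the
all-sample-standardized GRM on the pruned set, with a deterministic sign
convention (largest-magnitude coordinate positive). Subjects are
clustered by k-means on the eigenvector coordinates (k chosen by the
largest average silhouette over 2..8 when not fixed); labels are
relabeled by descending cluster size. Matched pairs are found per
cluster by exact minimum-total-distance assignment
(`scipy.optimize.linear_sum_assignment`) on Euclidean distances in the
eigenvector space; this replaces heuristic 1:1 matching with the same
objective solved exactly and deterministically. Clusters with cases but
no controls yield a warning and unmatched cases.

## Allele frequencies and GRMs

Frequencies come exclusively from the unmatched control pool — never the
analysis sample — to avoid leakage into the GRM. Per cluster k the
empirical-Bayes estimate is the beta-binomial posterior mean

    p̂_k = (c_k + m·p̄) / (2n_k + m),

with c_k the cluster allele count, p̄ the pooled frequency and prior
strength m = (1 − F̂)/F̂ from a moment estimate of across-cluster
divergence (floored at 20 to prevent degenerate no-shrinkage). Estimates
are clamped to [1/(2n+2), 1 − 1/(2n+2)]. Variants monomorphic in the
pool are excluded from GRM construction with a logged count; missing
dosages are mean-imputed to 2p (cluster-specific under CLS).

GRM modes: `CLS` and `POP` are Z Zᵀ/M on genotypes standardized with the
EB cluster or pooled frequencies respectively; `STD` is the GCTA default
on all-sample frequencies, whose diagonal uses the distinct
method-of-moments estimator 1 + mean[(x² − (1+2p)x + 2p²)/(2p(1−p))].
GRMs are written as GCTA binary triplets (.grm.bin/.grm.N.bin/.grm.id)
and TSV.

The motivating phenomenon — pooled-frequency standardization inflating
apparent relatedness inside minority clusters, removed by CLS — is
reproduced as a test at F = 0.05, m = 10,000, n = 400 with a 3:1 cluster
imbalance.

## G-BLUP and genomic control

Phenotypes are coded case = 1, control = 0 and centered per training
fold; coding is immaterial because GP is standardized afterwards
(mean 0, SD 1 across all scored subjects, jointly after all folds).
The ridge is λ = (1 − h²)/h² with h² fixed at 0.70.

Leave-pair-out folds reuse one inverse M = (K + λI)⁻¹ via the Schur
downdate (A₋S,₋S)⁻¹ = M₋S,₋S − M₋S,S(M_S,S)⁻¹M_S,₋S; the per-pair
prediction rows are cached so any new phenotype vector (permutation
nulls) is scored with one matrix-vector product. Exactness versus the
naive per-pair refit is tested to relative error ≤ 1e−8. If the SPD
solve fails, a 1e−8 diagonal jitter is applied once and logged.

Because the N−2/2 plan overfits, the Wald χ² of the case-control GP
contrast is deflated by genomic control: λ_GC = median(χ²)/0.4549 with
the median taken over a within-pair label-permutation null (200
permutations by default), floored at 1 for correction. The permutation
route is used because the inflation factor depends on the data at hand;
on simulated cohorts at the 500-pair scale it comes out around 2.4–2.6.

## PRS, WGRS, pTDT

PRS: allele alignment flips effect signs for swapped alleles and drops
strand-ambiguous (A/T, C/G) variants by default; clumping is greedy by
ascending p (ties by id) against an LD reference, which defaults to the
unmatched control pool; scoring mean-imputes missing dosages and
standardizes. Defaults p < 0.01, clump r² = 0.1, window 250 kb — the
sparse threshold keeps PRS only weakly correlated with GP so the two can
be usefully combined.

WGRS weights are wᵢ = R²ᵢ/ΣR² from each component's Nagelkerke pseudo-R²
for case-control separation, computed on the same matched sample being
analyzed. This induces an optimistic in-sample bias (the combined score's
pseudo-R² is guaranteed ≥ the best component only on the weighting data);
an equal-weights scheme is provided, and weights can be computed on a
held-out split by passing that split's status vector. If every component
has zero pseudo-R², equal weights are used with a warning.

pTDT: deviationᵢ = (childᵢ − midparentᵢ)/SD(midparent), one-sample
t-test of zero mean; invariant to adding a constant to all family
members.

Burden contrasts report group means (controls, all cases,
carrier/non-carrier cases, per-severity-class cases) with seeded
percentile bootstrap 95% CIs (2000 resamples) and a cases-only logistic
OR of carrier status on the score. Undetermined subjects are excluded
from carrier contrasts but retained as cases.

## Carrier classification

Qualifying PDVs: PTV in a risk gene; missense in a risk gene with
MPC strictly > 2; damaging CNV (any gene). Trisomy or large/multiple
CNVs force "undetermined" regardless of other records. Most severe class
by CNV > PTV > MIS. Subjects with no records are non-carriers — the
standard assumption when sequencing is incomplete; the risk-gene list is
an input file, and the simulator emits a synthetic one
(`RISK1..RISK20`).

## Problem sizes in the test suite

Simulation-based checks run at deliberately moderate scale, chosen as
the smallest sizes at which the tested effects are comfortably resolved:
GRM bias at n = 400 / m = 10,000; GP recovery at 500 matched pairs /
m = 5,000 / 500 causal variants; the additive-ordering battery at 40
seeds × 500 pairs / m = 2,000 / 200 causal variants (about 50 carrier
cases per seed); risk-ratio and prevalence moments on 2 × 10⁵
unascertained subjects. The full suite runs in a few minutes on one CPU.

## Known limitations

- The EB prior-strength estimator is a documented method-of-moments
  stand-in; alternative shrinkage recipes would change CLS frequencies
  slightly (not the qualitative bias repair).
- GP folds are standardized jointly after concatenation, not per fold.
- No REML: h² is always an input. No covariate-adjusted BLUP beyond
  regressing eigenvectors out of the phenotype.
- The pipeline's simulated-GWAS PRS path is an emulation hook; with real
  summary statistics, supply them via `prs.summary_stats` in the run
  config.
- `burden_contrasts` bootstrap CIs are percentile CIs; they do not
  account for the shared training folds across subjects' GP values.
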