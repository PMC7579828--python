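# Methods

`shedeval` implements a single-step genomic evaluation for early-summer
hair shedding score in beef cattle — a 1–5 visual score of remaining
winter coat (1 = fully shed) used as an indicator of heat tolerance and of
tolerance to toxic tall-fescue grazing — together with the validation and
association analyses that surround such an evaluation. Because the data
that motivated it are proprietary, the package carries its own synthetic-
herd generator, and every statistical claim the package makes is assessed
by recovery of known simulation truth or against an independent oracle.

## Models

**Prediction model.** A univariate repeated-records animal model

y = Xb + Z₁u + Z₂p + e,  u ~ N(0, H σ²ₐ),  p ~ N(0, I σ²ₚₑ),  e ~ N(0, I σ²ₑ)

with contemporary group (CG) fixed. The CG key is farm × year scored ×
calving season × fescue grazing status × age group (yearling / 2 / 3 /
other) × score group, where score groups are 7-day windows over scoring
dates assembled greedily (sort distinct dates; open a window at the
earliest unassigned date; take everything within 6 days; repeat — the
stated goal is maximizing animals per group, and greedy-by-earliest is
deterministic and near-optimal when scoring days cluster). CGs with fewer
than five animals or no score variation are dropped. Heritability is
h² = σ²ₐ/(σ²ₐ+σ²ₚₑ+σ²ₑ) and repeatability r = (σ²ₐ+σ²ₚₑ)/(σ²ₐ+σ²ₚₑ+σ²ₑ);
their standard errors come from the inverse average-information matrix by
the delta method.

**Age models.** Age in days is classified into windows
(n·365)−90 ≤ age < ((n+1)·365)−90; records younger than 275 days (the n=1
lower bound) are removed. Age enters as a categorical fixed effect —
age-in-years, four classes (1/2/3/other), or BIF age-of-dam classes — and
models are compared with AIC and likelihood-ratio tests. Because REML
likelihoods are not comparable across different fixed-effect structures,
`compare_models` evaluates the ML log-likelihood at the REML variance
estimates (|V| and the GLS residual quadratic form at b̂), which is
comparable across X and reduces to the usual statistic for nested fixed
effects.

**Fescue-status models.** (i) A bivariate model treating scores recorded
while grazing vs not grazing toxic fescue as two traits: genetic 2×2
covariance free over H, permanent-environment covariance fixed at 0, and —
a deliberate restriction — the cross-status residual covariance fixed at 0,
because the two statuses are never observed on the same record and that
parameter is unidentifiable. (ii) A univariate model with status as a
fixed effect (CG excludes status there); the reported contrast β_f is
not-grazing minus grazing, with grazing pinned at 0.

**Maternal weaning-weight model.** Dam hair shedding and calf weaning
weight are analyzed jointly: hair shedding carries a maternal (dam)
genetic effect only; weaning weight carries the calf's direct effect plus
the dam's maternal effect and maternal permanent environment. The three
genetic variates (u_WW, m_HS, m_WW) share one free 3×3 covariance over the
pedigree — the direct–maternal covariance must live inside one block or
the direct×maternal correlation would be structurally zero. Dams scored in
a year without a weighed calf get a "dummy calf" (unknown sire, missing
weight): the calf's effects remain estimable through relatives because a
missing response simply contributes no residual row. The residual HS–WW
covariance is fixed at 0 for the same non-co-observation reason as above.
Internally the kg-scale trait is standardized by its sample SD before
REML (a ~500-fold variance gap otherwise ruins the conditioning of the
information matrix) and components are mapped back afterwards.

## Relationship matrices

A is built by the tabular method; A⁻¹ by Henderson's rules with
Mendelian-sampling variances adjusted by the parents' inbreeding (F from
the tabular diagonal — adequate at the pedigree sizes this package
targets). G is VanRaden's ZZ′/2Σp(1−p) with observed allele frequencies
and per-SNP mean imputation of missing genotypes (keeps Z's columns at
mean zero). G is blended as G_w = 0.95·G + 0.05·A22 to restore full rank,
and the single-step inverse is H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A22⁻¹],
unscaled (no τ/ω weights). Genotype QC: SNP and animal call rate ≥ 85%,
monomorphic SNPs removed, and parent–offspring pairs with opposing-
homozygote rates above 2% have that parent link blanked (opposing
homozygotes only — robust without phase).

## REML

Variance components are estimated by average-information REML. All traces
are taken from the dense inverse of the mixed-model coefficient matrix;
at the package's design scale (2,000–4,000 equations) one LAPACK
`potrf`/`potri` per iteration is faster and far simpler than sparse
selected-inverse machinery. Newton steps are taken in an unconstrained
parametrization — the Cholesky factor of each free covariance block, the
log of each residual variance — with Levenberg–Marquardt damping adapted
so that a step is accepted only if the restricted likelihood does not
worsen; the first two iterations, and any iteration where no damped step
is acceptable, use the (monotone) EM update instead. Convergence is
declared when the largest relative component change falls below the
tolerance (default 1e-8; the replicate studies use 1e-6) or when the
likelihood change is below 1e-10 relative — the latter matters for
boundary ridges (e.g. a permanent-environment variance iterating toward
zero) where EM moves forever at flat likelihood. Points with a covariance
block within 1e-7 of singular are treated as outside the parameter space,
so boundary solutions (a genetic correlation estimated at ±1) sit just
inside. Fixed effects use a drop-first-level constraint per factor after
the first (which absorbs the intercept); an unestimable level falls back
to a tiny ridge on the fixed block with a warning, equivalent to a zero
constraint.

PEV of a breeding value is the corresponding diagonal of the inverse
coefficient matrix (residual scaling already folded into the equations),
and reliability = 1 − PEV/σ²ₐ clipped to [0, 1]. The two published
readings of "PEV = SE²·σ²ₑ" coincide under this scaling, so no switch is
needed.

## Validation and GWAS

The LR method masks all records of a random 25% of scored animals in each
of ten iterations and compares partial to whole EBVs: d = mean(whole −
partial) per set with |d| reported (a per-iteration mean can range to 0
under noise; a per-animal absolute mean cannot, which is why d is read as
the per-iteration mean), b = slope of whole on partial, ρ = Pearson
correlation. Partial fits reuse the whole-data variance components by
default. Without selection E[d] = 0 and E[b] = 1; the generator's
truncation-selection toggle exists to produce the dispersive negative
control.

GWAS deregresses EBVs as debv = EBV / r² with r² = 1 − PEV/σ²ₐ (simple
reliability deregression; parent-average stripping is a known alternative
not implemented) and weights records by r². Each SNP is tested by GLS
under y = 1μ + xβ + g + ε with Var(g) = G·σ²ₐ, Var(εᵢ) = σ²ₑ/wᵢ, the total
variance set to the sample variance of the debv and split 0.40/0.60 (the
heritability constraint). Wald p-values get Benjamini–Hochberg q-values
(the standard reading of a "genome-wide q-value"); genes whose span lies
within 50 kb of a q < 0.05 SNP are reported, strand-agnostic and inclusive
at exactly 50 kb.

## The synthetic herd

The generator mimics the study population at desk scale: a two-generation
random-mating pedigree (no selection, so the LR expectations hold);
unlinked gene-dropped SNPs (~50% of animals genotyped); infinitesimal
breeding values dropped down the pedigree with inbreeding-adjusted
Mendelian-sampling variance; 1–3 yearly scores per cow with farm×year CG
effects (SD 0.3 score units), a U-shaped age-class effect, a fescue
contrast of −0.59, and variance components (0.38, 0.04, 0.53) chosen so
h² = 0.40 and r ≈ 0.442 on a phenotypic total of 0.95. Scores are kept
continuous by default — the ordinal 1–5 score was analyzed as a linear
trait, so the linear scale is the faithful default — with an optional
1–5 discretization. The bivariate fescue truth comes from the per-status
table (phenotypic 0.90/0.95, additive 0.38/0.30, repeatability 0.45/0.34,
genetic correlation 0.93); the maternal truth uses the published
correlations (−0.19, −0.43, −0.03) with kg-scale variances (direct 200,
maternal 150, maternal PE 80, residual 300) typical of adjusted weaning
weights.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
unlinked, so GWAS power claims are about the scan machinery, not about
tagging causal variants), selection and assortative mating, genotype
imputation error, scoring-technician effects, and the real data's
record-count structure. Recovery of simulation truth therefore shows the
estimators are correct for the assumed model, not that the model is right
for real data.

## Study sizes and seeds

The replicate studies use ten replicates each at sizes chosen for a
single CPU: heritability/repeatability — ~1,260 pedigree animals, ~630
scored cows, ~1,100 records per replicate; cross-status correlation —
~700 animals, ~350 cows with 3–4 records and frequent within-cow status
switches (cows scored under both statuses are the analogue of the study's
dual-status animals and, with the PE covariance structurally zero, carry
most of the cross-trait information); maternal model — ~240 dams over
three calf crops plus their own historical weaning weights (without the
dams' own weights the direct–maternal covariance is nearly unidentified
and estimates swing to the boundary); LR-method calibration — ten 25%
partitions in each of five independent herds, summarized over herd means,
because partitions within one herd share its whole fit and occasionally
inherit a boundary variance estimate. Every stage derives its random
stream from one integer seed via `numpy` seed sequences; identical
configurations are bit-identical.

Recovery fits use A⁻¹ rather than H⁻¹: the generator's breeding values
are gene-dropped down the pedigree, so their true covariance is A, and
fitting with a marker-built H would misspecify the generator's own truth.
H⁻¹ is exercised (and oracle-tested against the direct joint-distribution
construction) in the pipeline path and the relationship-matrix suite.

## Known limitations

Dense per-iteration inversion caps practical problem size at roughly ten
thousand equations; the maternal-model correlation estimates at the
default study size carry large Monte-Carlo scatter (per-replicate SEs of
0.3–1.0), which the self-computed Monte-Carlo tolerance reflects
honestly; ordinal scores are treated as Gaussian throughout (no threshold
model); and the deregression does not strip parent averages.
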