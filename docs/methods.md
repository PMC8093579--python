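# Methods

This note documents the models and procedures implemented in `crcsig`,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic-data generators do and do
not emulate.

## Mutation catalog and channel model

Single-base substitutions are classified into the 96 pyrimidine-centric
trinucleotide channels: six substitution types (C>A, C>G, C>T, T>A,
T>C, T>G) × 16 flanking-base contexts, in fixed COSMIC v2 order (C>A
block first, contexts alphabetical within a block). A substitution
reported on the purine strand is reverse-complemented together with its
context, so classification is strand-symmetric and idempotent under
reverse-complement presentation.

MAF coordinates are 1-based inclusive (GDC dialect); the flanking bases
of position *p* are looked up at [p−1, p+1] in the reference FASTA.
Indels and multi-nucleotide variants are retained as records (they
count toward total burden) but never enter the 96-channel catalog,
which is an SNV-only model. A mutation whose stated reference allele
disagrees with the FASTA is dropped and counted in the reject log, never
silently repaired: allele flips usually indicate a build mismatch, and
repairing them would hide it. Chromosomes absent from the reference
fail loudly by default (`missing_chrom="skip"` downgrades to a logged
reject).

The NMF input is the raw count matrix by default. Per-sample frequency
normalization (`use_frequencies=True`) is supported; raw counts are the
default because the multiplicative KL updates already weight samples by
their mutation load, which is the behaviour of the factorization tools
this field uses.

## APOBEC tCw enrichment

For each sample the fold enrichment of APOBEC-type mutations in the
tCw motif (w ∈ {A, T}) is

E = (n_mut_tCw / n_mut_C) / (ctx_tCw / ctx_C),

where the "mutated" sets count C>T and C>G substitutions (the
APOBEC-type changes) — n_mut_tCw at tCw sites, n_mut_C at any cytosine
— and the background counts tally tCw motifs and cytosines in ±20-base
windows around each mutated cytosine, on both strands (wGa is tCw on
the reverse strand). Restricting both numerator and denominator to
C>T/C>G is required for internal consistency: it makes E an estimate of
motif preference alone, so that under uniform placement of APOBEC-type
mutations over cytosines E → 1 (the null-calibration property the test
suite checks). Significance is a one-sided Fisher exact test on
[[n_mut_tCw, n_mut_C − n_mut_tCw], [ctx_tCw, ctx_C − ctx_tCw]], BH-
corrected across samples. Samples with no APOBEC-type mutation or an
empty tCw background are flagged not evaluable rather than scored 0.

Background windows are fetched with one extra base on each side so that
every position of the ±20 core can be motif-evaluated with its true
neighbours; counting cytosines over a window whose edge bases cannot be
scanned would deflate the background ratio by about 5% and bias E
upward. A smaller residual (~+4% in the null simulations) remains and
is structural to window-centered counting — the two positions adjacent
to a window's central C/G can never themselves be tCw motifs; it is a
property of the published enrichment construction, not of this
implementation.

## Signature factorization and rank selection

The catalog V (96 × n) is factorized V ≈ P·E by Lee–Seung
multiplicative updates under the generalized Kullback–Leibler
divergence (the classical variant for mutation signatures); a Frobenius
objective is available behind a flag. Profiles are column-normalized to
probability vectors with exposures rescaled so P·E is unchanged (to
1e-9). Defaults: 30 restarts, 2000 iterations, relative-objective
tolerance 1e-6; the objective trace is retained and is non-increasing
by construction of the updates. All-zero samples are legal and receive
zero exposure.

For rank selection, each restart's hard assignment (argmax exposure per
sample) defines a co-assignment consensus matrix over restarts; the
cophenetic correlation between 1 − consensus and the ultrametric
distances of its average-linkage dendrogram measures restart stability.
The chosen rank maximizes the cophenetic coefficient, ties broken
toward the smaller rank; RSS of the best restart is reported as a
secondary diagnostic, not an automatic criterion, because cophenetic
stability and residual fit do not share a scale on which to arbitrate.
Annotation maps each profile to the nearest reference signature by
cosine similarity (ties toward the lower-numbered signature);
many-to-one mappings are legal and flagged.

### Synthetic signature reference

The packaged reference table is **synthetic**: 30 deterministic sparse
Dirichlet profiles (concentration 0.1, fixed per-signature seed
streams) named "Signature 1" … "Signature 30" in the COSMIC v2 layout.
Sparse profiles make nearest-cosine annotation nearly unambiguous
(planted trios used in tests have pairwise cosine < 0.3), which is what
recovery tests need. A genuine COSMIC v2 table in the same layout can
be supplied to `load_reference` for real analyses. Conclusions about
real COSMIC signatures (e.g. flat, highly collinear signatures 3/5/8)
do not follow from tests on the synthetic table.

## Consensus clustering and PAC

Per iteration, ⌊0.8·n⌋ samples are drawn without replacement and
partitioned by k-means (k-means++, 10 inner restarts, Euclidean
distance) for each k in 2…9; the consensus entry (i, j) is
co-clustered / co-sampled counts, undefined (and excluded from the CDF)
for never co-sampled pairs. PAC is the fraction of defined
lower-triangle entries in (0.1, 0.9] — the standard interval — and the
chosen k minimizes PAC with ties toward smaller k. Final labels come
from average-linkage clustering of 1 − consensus cut at k (mean-imputed
missing entries), with cluster ids ordered by decreasing size. The
clustering features are per-sample exposure *fractions* (exposures
normalized to sum 1): clustering unnormalized exposures would group
samples by mutation burden alone, confounding the process composition
the signatures describe. A flag overrides this.

## Survival kernel

Kaplan–Meier, the k-group log-rank test, and Cox proportional-hazards
regression (Newton–Raphson on the Efron partial likelihood, with
step-halving) are implemented directly; `lifelines` serves as an
independent oracle in the tests (agreement to 1e-6 on fixtures).
Implementing the kernel in-package keeps two exact contracts that
delegation would lose: the two-group log-rank statistic equals the Cox
score test at β = 0 on tie-free data, and separation or monotone
likelihood (e.g. all events in one level of a binary covariate) is
flagged `non_estimable` with NaN Wald p-values instead of a huge finite
hazard ratio. Constant covariates are non-estimable; collinear columns
are dropped with a record. Convergence: |Newton step| < 1e-9 within
100 iterations; |β| > 15 is treated as monotone likelihood.

BH adjustment is the step-up definition with enforced monotonicity.
2×2 tables use Fisher's exact test (two-sided, point-probability
method, via scipy) when any expected count is below 5 or any observed
cell is zero, otherwise Pearson chi-squared without continuity
correction; odds ratios get a Haldane 0.5 correction on zero cells, and
a zero margin yields p = 1 with no odds ratio. Wilcoxon tests use the
exact null for small tie-free samples and the tie-corrected normal
approximation otherwise.

Methylation beta values binarize at 0.3, with the boundary counting as
methylated (the threshold is configurable; the boundary convention is a
documented choice). The silencing screen flags a gene when the
methylated group's mean expression is lower than the unmethylated
group's by at least `min_abs_diff` (default 1.0 on a log-like scale)
with Wilcoxon p < 0.05; both thresholds are configurable because the
upstream criterion defers them to a citation. Direction matters: a
methylated-higher gene is never flagged.

## Gene-pair screen and the CPGPS rule

The pair encoding is deliberately primitive: state(A|B) = 1 if
expression of A strictly exceeds B, 0 if B exceeds A, missing on exact
equality (the sample is discarded for that pair — no epsilon, because
an epsilon would break invariance under monotone transforms).
Everything downstream consumes only these states, which is what makes
the whole module bit-identical under any strictly monotone per-cohort
transform of expression — the property that frees the biomarker from
batch effects and cutoffs.

Per cohort, a pair whose dominant state exceeds 90% of informative
samples is excluded *from that cohort only* (strictly greater than
0.90; exactly 90.0% is retained). Exclusion is per-cohort rather than
global because a pair can be uninformative on one platform yet balanced
on others. Retained pairs are screened by univariate Cox regression on
the binary state (Efron ties), with BH FDR across the cohort's retained
estimable pairs. The consensus rule: FDR < 0.05 in at least 6 cohorts
("more than five" read strictly), counting only cohorts where the pair
is retained and estimable. Direction consistency (sign agreement of the
log hazard ratio across significant cohorts) is reported. Metastasis
association uses the state × M0/M1 2×2 table with the Fisher/chi-square
arbitration above; independence is assessed by a multivariable Cox fit
of the state plus clinical covariates.

The DEG screen feeding the candidate list is a documented stand-in for
a negative-binomial DE test: library-size-normalized counts, log2FC
with pseudocount 1, per-gene two-sided Wilcoxon rank-sum p, BH FDR,
thresholds |log2FC| > 1 and FDR < 0.05; a precomputed gene list can be
supplied instead, which is also the bridge for users who ran a
dedicated DE tool.

## Synthetic data: what it emulates, and what it does not

`simulate_catalog` draws per-sample exposures from Dirichlet(α),
mutation counts from Poisson, and channel counts from the multinomial
mixture of planted profiles — the exact generative model the NMF
assumes, so recovery tests measure the estimator, not model mismatch.
Real catalogs add strand biases, regional mutation-rate covariates and
inter-signature correlation that this generator does not emulate.

`simulate_cohorts` plants one prognostic pair: a latent state z ~
Bernoulli(0.5) per sample sets the pair orientation (gene A ~
N(μ+0.5, 0.25), gene B ~ N(μ−0.5, 0.25) for z = 1, swapped otherwise),
giving a within-pair crossover probability of 0.0023 (< the 0.01 bound,
enforced at spec validation). The pair contrast is deliberately small
in *absolute* terms: only the A-versus-B comparison, not either gene's
marginal level, carries z, so pairs of a planted gene with a noise gene
are nearly uninformative — without this, every such cross pair becomes
a genuine secondary biomarker and recovery experiments cannot count
false positives meaningfully. Candidate ("DEG-like") genes carry
moderate subtype shifts (|shift| ~ U(0.15, 0.45), random sign, means
within ±0.3 of μ), emulating the structure of a real DEG-derived
candidate list where many pairs are weakly informative; this populates
the within-cohort p-value distribution realistically and shares the BH
burden the way real candidate lists do. Remaining genes are independent
noise with gene-intrinsic levels (sd 2.0 across genes) shared across
cohorts. Survival is exponential with hazard λ0·HR^z — constant
baseline hazard, so proportional hazards holds exactly and the planted
HR is the estimand — under independent Uniform(0, 60) censoring.
λ0 = 0.12 per time unit gives ≈ 87% events: censoring is deliberately
light because the recovery experiments demand within-cohort FDR
significance in *all six* generated cohorts, a stricter bar than the
more-than-five-of-eleven rule the screen applies to real cohort
collections; the time unit is arbitrary. Metastasis is Bernoulli per
state (defaults 0.40 vs 0.15). Finally each cohort's expression matrix
passes through a distinct strictly monotone batch transform (identity,
exp, affine, cube, logistic, softplus) — the invariance tests compare
against an identity-transform run of the same seeds.

What passing these tests shows: the estimators recover the planted
structure under their own model assumptions and the pair module is
exactly rank-based. What they do not show: robustness to microarray
normalization artifacts, cohort heterogeneity in endpoint definitions,
gene-identifier mismatches, or non-proportional hazards.

## Problem sizes and numerical choices

Recovery experiments use 200 samples × ~100 mutations for signatures
(rank search 2–6, 10 restarts), n = 100 × 20 replicates at 200
consensus iterations for clustering, and 6 cohorts × 150 samples × 400
genes (20 candidate genes, 190 pairs) for the pair screen — sizes at
which every planted effect is identifiable while the full suite runs on
one CPU in minutes. Production defaults are larger (30 restarts, ranks
2–10, 1000 consensus iterations). Ties in rank/k selection break toward
the smaller model; cosine similarity of a zero vector is an error, not
0; consensus entries for never co-sampled pairs are missing, not 0; BH
inputs outside [0, 1] are fatal. The master seed spawns per-stage
substreams (stage-indexed `SeedSequence`), so adding a stage never
perturbs earlier stages' randomness.
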