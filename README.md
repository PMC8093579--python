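# crcsig

Mutational-signature subtyping and rank-based gene-pair biomarker
discovery for colorectal cancer (CRC) cohorts.

Somatic mutation catalogs carry the fingerprints of the processes that
generated them, and bulk expression cohorts carry prognostic structure
that is hard to transfer between platforms. `crcsig` implements the
full computational chain connecting the two:

1. **96-channel mutation catalog** — single-base substitutions from a
   MAF file are collapsed onto the pyrimidine strand and classified by
   substitution type and flanking bases (6 × 16 = 96 channels, fixed
   COSMIC v2 order), using a reference FASTA for context lookup.
2. **Signature extraction** — non-negative matrix factorization
   V ≈ P·E of the catalog under the generalized Kullback–Leibler
   divergence (multiplicative updates, best of restarts), with the rank
   chosen by the cophenetic correlation of the restart-consensus matrix
   (RSS reported as a secondary diagnostic) and extracted profiles
   annotated against a reference signature table by cosine similarity.
3. **Consensus clustering** — samples are repeatedly subsampled (80%)
   and partitioned by Euclidean k-means; the number of clusters
   minimizes the proportion of ambiguous clustering, PAC = F(0.9) −
   F(0.1) of the consensus CDF.
4. **APOBEC tCw enrichment** — per-sample fold enrichment
   E = (n_tCw/n_C) / (ctx_tCw/ctx_C) of APOBEC-type (C>T, C>G)
   mutations in the tCw motif (w ∈ {A,T}) over motif availability in
   ±20 bp windows, with a one-sided Fisher test and BH correction.
5. **Gene-pair biomarkers (CPGPS)** — for each gene pair A|B, the
   binary per-sample feature "expression of A exceeds B" is screened by
   univariate Cox regression in every cohort; a pair with FDR < 0.05 in
   more than five cohorts is a consensus prognosis gene pair signature.
   Because the feature depends only on within-sample ranks it is
   invariant to any strictly monotone platform or batch distortion and
   needs no expression cutoff.

A seeded synthetic-data module generates every input with planted
ground truth (signature mixtures, toy genome + MAF, multi-cohort
expression/survival data with a planted prognostic pair), so the whole
pipeline runs and is tested without any external download.

## Worked example

```python
from crcsig import (CatalogSimSpec, SignatureModel, ConsensusCluster,
                    GenePairScreen, CohortSimSpec, load_reference,
                    simulate_catalog, simulate_cohorts)

# --- signatures: 200 samples drawn from 3 planted profiles ---------
cat, truth = simulate_catalog(CatalogSimSpec(seed=7))
model = SignatureModel(cat)
sel = model.select_rank(range(2, 7), n_restarts=10, seed=7)
print(sel.metrics.round(3))
#       cophenetic        rss  chosen
# rank
# 2          0.916  31492.537   False
# 3          0.996  17220.181    True
# 4          0.972  16968.096   False
# 5          0.930  16522.078   False
# 6          0.895  16184.507   False
print(sel.best.annotate(load_reference())["best_match"].tolist())
# ['Signature 10', 'Signature 1', 'Signature 6']

# --- subtypes: consensus clustering of exposure fractions ----------
cc = ConsensusCluster(sel.best.exposure_fractions().T).fit(
    k_max=9, n_iter=200, seed=0)
print(cc.chosen_k)   # number of mutational-signature clusters

# --- gene pairs: multi-cohort prognostic screen --------------------
cohorts, ctruth = simulate_cohorts(
    CohortSimSpec(seed=3, cohort_seeds=(1, 2, 3, 4, 5, 6)))
res = GenePairScreen(cohorts, ctruth.candidate_genes).fit()
print(res.summary())
#                n_significant  n_evaluable  direction_consistent  mean_log_hr
# pair
# GENE_A|GENE_B              6            6                  True     1.035218
```

The rank-selection table shows the cophenetic correlation peaking at
the planted rank 3; the annotation maps each extracted profile to its
planted reference signature.  The pair screen returns exactly the
planted pair as a CPGPS: significant (within-cohort FDR < 0.05) in all
6 cohorts with a consistent hazard direction (state A>B carries a mean
log hazard ratio of about 1.0 ≈ log 2.5, the planted effect).

The same stages are available from the shell:

```bash
crcsig simulate cohorts --seed 3 --out sim/
crcsig pairs --manifest sim/manifest.yaml --deg sim/candidate_genes.txt \
       --min-cohorts 6 --out out/
crcsig run-all --seed 7 --out run/        # full simulated pipeline
```

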