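"""Rank-based gene-pair prognostic and metastasis biomarker discovery.

A gene pair A|B encodes, per sample, whether gene A's expression exceeds
gene B's.  Because the encoding depends only on the within-sample rank
of the two genes, it is invariant to any strictly monotone per-cohort
transform — platform and batch effects vanish, and no expression cutoff
is ever needed.  The pipeline:

1.  DEG screen between two sample groups (library-size-normalised
    log2 fold change with pseudocount 1 + Wilcoxon rank-sum + BH FDR;
    a precomputed gene list can be supplied instead).
2.  Ternary pair matrix over all unordered DEG pairs; ties (exactly
    equal expression) are discarded per sample.
3.  Per-cohort imbalance filter: a pair whose dominant state exceeds
    90% of informative samples is dropped in that cohort only.
4.  Per-cohort univariate Cox screen of each retained pair (Efron
    ties), BH FDR within cohort.
5.  Consensus rule: a pair significant (FDR < 0.05) in more than five
    cohorts is a consensus prognosis gene pair signature (CPGPS).
6.  Metastasis association of each CPGPS (Fisher/chi-squared) and a
    multivariable independence check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survstats import CoxResults, bh_fdr, cox_fit, fisher_or_chisq, wilcoxon_tests

A_GT_B = 1.0
B_GT_A = 0.0


# --------------------------------------------------------------------- cohort

@dataclass
class ExpressionCohort:
    """One expression cohort with matched clinical annotations.

    ``expr`` is genes x samples; ``clinical`` is indexed by sample with
    columns ``time`` (same unit within the cohort), ``event`` (0/1) and
    optionally ``metastasis`` ("M0"/"M1", else missing).
    """

    cohort_id: str
    expr: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        self.expr.columns = self.expr.columns.astype(str)
        self.clinical.index = self.clinical.index.astype(str)
        common = [s for s in self.expr.columns if s in set(self.clinical.index)]
        if not common:
            raise ValueError(f"{self.cohort_id}: no samples shared between "
                             "expression and clinical tables")
        self.expr = self.expr[common]
        self.clinical = self.clinical.loc[common]
        if self.clinical.index.duplicated().any():
            raise ValueError(f"{self.cohort_id}: duplicate sample ids")
        if (self.clinical["time"] < 0).any():
            raise ValueError(f"{self.cohort_id}: negative survival time")

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    def has_metastasis_info(self) -> bool:
        return (
            "metastasis" in self.clinical.columns
            and self.clinical["metastasis"].isin(["M0", "M1"]).any()
        )


# ----------------------------------------------------------------- DEG screen

def deg_screen(
    counts: pd.DataFrame,
    labels,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression screen between two groups.

    Counts are library-size normalised (columns scaled to the mean
    library size); log2FC = log2((mean_A + c) / (mean_B + c)) with
    pseudocount c; per-gene two-sided Wilcoxon rank-sum p; BH FDR.
    Genes pass with |log2FC| > lfc_min and FDR < fdr_max.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, p, fdr, selected``.
    """
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if levels.size != 2:
        raise ValueError("deg_screen requires exactly two groups")
    in_a = labels == levels[0]
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib = np.where(lib > 0, lib, 1.0)
    norm = counts.to_numpy(dtype=float) / lib * lib.mean()
    mean_a = norm[:, in_a].mean(axis=1)
    mean_b = norm[:, ~in_a].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pvals = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        pvals[i] = wilcoxon_tests(norm[i, in_a], norm[i, ~in_a])[1]
    fdr = bh_fdr(pvals)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "fdr": fdr}, index=counts.index
    )
    out["selected"] = (np.abs(out["log2fc"]) > lfc_min) & (out["fdr"] < fdr_max)
    return out


# ---------------------------------------------------------------- pair matrix

def pair_label(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}|{gene_b}"


def build_pair_matrix(expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Ternary pair-state matrix over all unordered gene pairs.

    Rows are pairs "A|B" (A < B lexicographically), columns are
    samples; entries are 1.0 (A > B), 0.0 (B > A) or NaN (equal
    expression — the sample is discarded for that pair, or a gene is
    absent from the cohort, which makes the whole row NaN).
    """
    genes = sorted(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    n_samp = expr.shape[1]
    rows = {}
    present = {g: g in expr.index for g in genes}
    for a, b in itertools.combinations(genes, 2):
        if not (present[a] and present[b]):
            rows[pair_label(a, b)] = np.full(n_samp, np.nan)
            continue
        ea = expr.loc[a].to_numpy(dtype=float)
        eb = expr.loc[b].to_numpy(dtype=float)
        state = np.where(ea > eb, A_GT_B, np.where(eb > ea, B_GT_A, np.nan))
        rows[pair_label(a, b)] = state
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)


def imbalance_filter(pair_matrix: pd.DataFrame, max_fraction: float = 0.90) -> pd.DataFrame:
    """Per-cohort pair retention under the dominant-state rule.

    A pair is excluded from this cohort when either state's fraction
    among informative (non-missing) samples strictly exceeds
    *max_fraction*; 90.0% exactly is retained.  Pairs with no
    informative sample are not evaluable.

    Returns a DataFrame indexed by pair with columns
    ``n_informative, frac_a_gt_b, retained, evaluable``.
    """
    M = pair_matrix.to_numpy(dtype=float)
    n_inf = (~np.isnan(M)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_a = np.nansum(M == A_GT_B, axis=1) / np.where(n_inf > 0, n_inf, 1)
    evaluable = n_inf > 0
    dominant = np.maximum(frac_a, 1.0 - frac_a)
    retained = evaluable & (dominant <= max_fraction)
    return pd.DataFrame(
        {
            "n_informative": n_inf,
            "frac_a_gt_b": np.where(evaluable, frac_a, np.nan),
            "retained": retained,
            "evaluable": evaluable,
        },
        index=pair_matrix.index,
    )


# ----------------------------------------------------------------- Cox screen

def screen_pairs(
    pair_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    max_fraction: float = 0.90,
    min_events: int = 10,
) -> pd.DataFrame:
    """Univariate Cox screen of every retained pair in one cohort.

    Each pair's binary state (A>B = 1) is the sole covariate of a
    proportional-hazards fit (Efron ties); samples with a missing state
    are dropped pairwise.  Wald p-values are BH-adjusted across all
    retained, estimable pairs within the cohort.  Cohorts with fewer
    than *min_events* events are flagged low-power.

    Returns a DataFrame indexed by pair with columns ``n, n_events,
    log_hr, hr, se, p, fdr, retained, evaluable, estimable,
    low_power``.
    """
    filt = imbalance_filter(pair_matrix, max_fraction)
    samples = [s for s in pair_matrix.columns if s in set(clinical.index)]
    clin = clinical.loc[samples]
    times_all = clin["time"].to_numpy(dtype=float)
    events_all = clin["event"].to_numpy(dtype=int)
    low_power_cohort = events_all.sum() < min_events

    rows = []
    for pair in pair_matrix.index:
        state = pair_matrix.loc[pair, samples].to_numpy(dtype=float)
        ok = ~np.isnan(state)
        rec = {
            "pair": pair,
            "n": int(ok.sum()),
            "n_events": int(events_all[ok].sum()),
            "log_hr": np.nan, "hr": np.nan, "se": np.nan, "p": np.nan,
            "retained": bool(filt.loc[pair, "retained"]),
            "evaluable": bool(filt.loc[pair, "evaluable"]),
            "estimable": False,
            "low_power": low_power_cohort,
        }
        if rec["retained"] and ok.sum() >= 2 and events_all[ok].sum() >= 1:
            x = state[ok]
            if np.ptp(x) > 0:
                fit = cox_fit(times_all[ok], events_all[ok], x[:, None],
                              names=["state"])
                if not fit.non_estimable:
                    rec.update(
                        log_hr=float(fit.params[0]), hr=float(np.exp(fit.params[0])),
                        se=float(fit.bse[0]), p=float(fit.pvalues[0]),
                        estimable=True,
                    )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("pair")
    valid = out["p"].notna() & out["retained"]
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out


# ------------------------------------------------------------- consensus rule

def consensus_select(
    screens: dict[str, pd.DataFrame],
    min_cohorts: int = 6,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Consensus prognosis gene pair signatures across cohorts.

    A pair qualifies when its within-cohort FDR is below *fdr_max* in at
    least *min_cohorts* cohorts ("more than five" read strictly as >= 6);
    only cohorts where the pair is retained and estimable count.
    Direction consistency records whether the sign of the log hazard
    ratio agrees across all significant cohorts.
    """
    if not screens:
        return pd.DataFrame(
            columns=["n_significant", "n_evaluable", "significant_cohorts",
                     "direction_consistent", "mean_log_hr"]
        )
    all_pairs = sorted({p for df in screens.values() for p in df.index})
    rows = []
    for pair in all_pairs:
        sig_cohorts = []
        log_hrs = []
        n_eval = 0
        for cid, df in screens.items():
            if pair not in df.index:
                continue
            rec = df.loc[pair]
            if not (rec["retained"] and rec["estimable"]):
                continue
            n_eval += 1
            if pd.notna(rec["fdr"]) and rec["fdr"] < fdr_max:
                sig_cohorts.append(cid)
                log_hrs.append(float(rec["log_hr"]))
        if len(sig_cohorts) >= min_cohorts:
            signs = np.sign(log_hrs)
            rows.append(
                {
                    "pair": pair,
                    "n_significant": len(sig_cohorts),
                    "n_evaluable": n_eval,
                    "significant_cohorts": sig_cohorts,
                    "direction_consistent": bool(np.all(signs == signs[0])),
                    "mean_log_hr": float(np.mean(log_hrs)),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["pair", "n_significant", "n_evaluable", "significant_cohorts",
                 "direction_consistent", "mean_log_hr"],
    )
    return out.set_index("pair")


# ----------------------------------------------------------------- metastasis

def metastasis_association(
    pair_state: pd.Series, metastasis: pd.Series
) -> dict:
    """Association of one pair's state with distant metastasis (M0/M1).

    Builds the 2x2 table state x metastasis over samples with both
    values present; Fisher exact when any expected count < 5, Pearson
    chi-squared otherwise; Haldane-corrected odds ratio on zero cells.
    """
    common = [s for s in pair_state.index if s in set(metastasis.index)]
    st = pair_state.loc[common].to_numpy(dtype=float)
    mt = metastasis.loc[common]
    keep = ~np.isnan(st) & mt.isin(["M0", "M1"]).to_numpy()
    st, mt = st[keep], mt[keep]
    m1 = (mt == "M1").to_numpy()
    table = np.array(
        [
            [int(((st == A_GT_B) & m1).sum()), int(((st == A_GT_B) & ~m1).sum())],
            [int(((st == B_GT_A) & m1).sum()), int(((st == B_GT_A) & ~m1).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0:  # a pair state absent
        return {"table": table, "p": np.nan, "odds_ratio": np.nan,
                "test": "not_evaluable", "evaluable": False,
                "rate_a_gt_b": np.nan, "rate_b_gt_a": np.nan}
    res = fisher_or_chisq(table)
    return {
        "table": table,
        "p": res["p"],
        "odds_ratio": res["odds_ratio"],
        "test": res["test"],
        "evaluable": True,
        "rate_a_gt_b": table[0, 0] / table[0].sum(),
        "rate_b_gt_a": table[1, 0] / table[1].sum(),
    }


def assess_independence(
    pair_state: pd.Series,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> CoxResults:
    """Multivariable Cox fit of a pair state alongside clinical covariates.

    With no covariates this reduces to the univariate screen fit.  The
    pair is called an independent prognostic factor when its Wald p is
    below 0.05 with the covariates present; constant or collinear
    covariates are dropped with a record.
    """
    common = [s for s in pair_state.index if s in set(clinical.index)]
    st = pair_state.loc[common]
    clin = clinical.loc[common]
    keep = st.notna()
    if covariates is not None:
        covariates = covariates.loc[[s for s in common if s in covariates.index]]
        keep &= pd.Series(
            [s in covariates.index and not covariates.loc[s].isna().any()
             for s in common], index=common,
        )
    st, clin = st[keep], clin[keep]
    X = pd.DataFrame({"state": st.to_numpy(dtype=float)}, index=st.index)
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates.loc[st.index, c].to_numpy(dtype=float)
    return cox_fit(
        clin["time"].to_numpy(dtype=float),
        clin["event"].to_numpy(dtype=int),
        X,
    )


# ---------------------------------------------------------------- model class

@dataclass
class GenePairResults:
    """Fitted multi-cohort gene-pair screen."""

    screens: dict[str, pd.DataFrame]
    cpgps: pd.DataFrame
    metastasis: pd.DataFrame
    genes: list[str]
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        if self.cpgps.empty:
            return self.cpgps
        return self.cpgps[["n_significant", "n_evaluable",
                           "direction_consistent", "mean_log_hr"]]


class GenePairScreen:
    """Multi-cohort gene-pair prognostic screen (statsmodels-style).

    Parameters
    ----------
    cohorts
        Expression cohorts with survival annotations.
    genes
        Candidate gene list (e.g. a DEG list).  Pair enumeration is
        quadratic in its length.
    """

    def __init__(self, cohorts: list[ExpressionCohort], genes):
        if not cohorts:
            raise ValueError("need at least one cohort")
        self.cohorts = list(cohorts)
        self.genes = sorted(dict.fromkeys(genes))

    def fit(
        self,
        min_cohorts: int = 6,
        fdr_max: float = 0.05,
        max_fraction: float = 0.90,
        min_events: int = 10,
    ) -> GenePairResults:
        screens: dict[str, pd.DataFrame] = {}
        pair_matrices: dict[str, pd.DataFrame] = {}
        for cohort in self.cohorts:
            pm = build_pair_matrix(cohort.expr, self.genes)
            pair_matrices[cohort.cohort_id] = pm
            screens[cohort.cohort_id] = screen_pairs(
                pm, cohort.clinical, max_fraction, min_events
            )
        cpgps = consensus_select(screens, min_cohorts, fdr_max)

        met_rows = []
        for cohort in self.cohorts:
            if not cohort.has_metastasis_info():
                continue
            pm = pair_matrices[cohort.cohort_id]
            for pair in cpgps.index:
                if pair not in pm.index:
                    continue
                res = metastasis_association(
                    pm.loc[pair], cohort.clinical["metastasis"]
                )
                met_rows.append(
                    {
                        "cohort": cohort.cohort_id,
                        "pair": pair,
                        "p": res["p"],
                        "odds_ratio": res["odds_ratio"],
                        "test": res["test"],
                        "rate_a_gt_b": res["rate_a_gt_b"],
                        "rate_b_gt_a": res["rate_b_gt_a"],
                        "evaluable": res["evaluable"],
                    }
                )
        metastasis = pd.DataFrame(
            met_rows,
            columns=["cohort", "pair", "p", "odds_ratio", "test",
                     "rate_a_gt_b", "rate_b_gt_a", "evaluable"],
        )
        return GenePairResults(
            screens, cpgps, metastasis, self.genes,
            params={"min_cohorts": min_cohorts, "fdr_max": fdr_max,
                    "max_fraction": max_fraction, "min_events": min_events},
        )
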