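"""Survival and shared statistical kernel.

Product-limit (Kaplan-Meier) estimation, the k-group log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the Efron partial
likelihood, Benjamini-Hochberg step-up adjustment, Fisher/chi-squared
arbitration for 2x2 tables, Wilcoxon tests, and the methylation
binarization / expression-silencing screen.

The survival estimators are implemented here directly (rather than
delegated) so that exact contracts hold: the two-group log-rank
statistic equals the Cox score test at beta = 0 on tie-free data, and
separation/non-convergence is flagged explicitly instead of returning a
huge finite hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KaplanMeierResult",
    "km_estimate",
    "logrank_test",
    "CoxResults",
    "cox_fit",
    "bh_fdr",
    "fisher_or_chisq",
    "wilcoxon_tests",
    "methylation_binarize",
    "silencing_screen",
]


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KaplanMeierResult:
    """Product-limit survival estimate with its risk table."""

    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # number at risk just before each event time
    n_events: np.ndarray     # events at each event time
    n: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """S(t), right-continuous step function with S(0) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        out = np.concatenate(([1.0], self.survival))[idx]
        return out if out.size > 1 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate(([0.0], self.event_times))
        s = np.concatenate(([1.0], self.survival))
        ax.step(t, s, where="post", **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    ``events`` is 1 for an observed event, 0 for right censoring.
    """
    times, events = _check_surv(times, events)
    if times.size == 0:
        raise ValueError("no observations")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    ev_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in ev_times])
    n_ev = np.array([((times == t) & (events == 1)).sum() for t in ev_times])
    surv = np.cumprod(1.0 - n_ev / at_risk) if ev_times.size else np.array([])
    return KaplanMeierResult(ev_times, surv, at_risk, n_ev, n=times.size)


# -------------------------------------------------------------------- log-rank

def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-squared statistic, p).

    With two groups the statistic has 1 degree of freedom and equals the
    Cox partial-likelihood score test on the group indicator when event
    times are untied.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    k = levels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if events.sum() == 0:
        raise ValueError("need at least one event")
    for lv in levels:
        if (groups == lv).sum() == 0:
            raise ValueError(f"empty group {lv!r}")

    ev_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_g = np.array([(at_risk & (groups == lv)).sum() for lv in levels], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (groups == lv)).sum() for lv in levels],
            dtype=float,
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (
                d
                * (n - d)
                / (n - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    u = (O - E)[:-1]
    v = V[:-1, :-1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    p = float(stats.chi2.sf(stat, df=k - 1))
    return stat, p


# ------------------------------------------------------------------------- Cox

@dataclass
class CoxResults:
    """Cox proportional-hazards fit (Efron partial likelihood)."""

    params: np.ndarray      # log hazard ratios
    bse: np.ndarray         # standard errors
    names: list[str]
    n: int
    n_events: int
    loglik: float
    converged: bool
    non_estimable: bool
    n_iter: int
    score_stat: float = np.nan   # score test at beta = 0 (all covariates)
    score_p: float = np.nan
    dropped: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Wald p-values; NaN when the fit is non-estimable."""
        if self.non_estimable:
            return np.full_like(self.params, np.nan)
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )


def _efron_quantities(beta, times, events, X):
    """Log-likelihood, gradient and information of the Efron partial likelihood.

    Risk-set sums are accumulated with grouped cumulative sums over the
    distinct times (descending), leaving an explicit loop only over
    event-time groups.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    ts = times[order]
    ev = events[order].astype(bool)
    Xs = X[order]
    ws = w[order]
    etas = eta[order]
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    wx = ws[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    S0 = np.cumsum(np.add.reduceat(ws, starts))
    S1 = np.cumsum(np.add.reduceat(wx, starts, axis=0), axis=0)
    S2 = np.cumsum(np.add.reduceat(wxx, starts, axis=0), axis=0)
    evf = ev.astype(float)
    D0 = np.add.reduceat(ws * evf, starts)
    D1 = np.add.reduceat(wx * evf[:, None], starts, axis=0)
    D2 = np.add.reduceat(wxx * evf[:, None, None], starts, axis=0)
    Dn = np.add.reduceat(evf, starts).astype(int)
    Eeta = np.add.reduceat(etas * evf, starts)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for g in np.flatnonzero(Dn):
        d = Dn[g]
        loglik += Eeta[g]
        for ell in range(d):
            f = ell / d
            a0 = S0[g] - f * D0[g]
            a1 = S1[g] - f * D1[g]
            a2 = S2[g] - f * D2[g]
            loglik -= np.log(a0)
            gt = a1 / a0
            grad -= gt
            info += a2 / a0 - np.outer(gt, gt)
    # sum of event covariates
    grad += Xs[ev].sum(axis=0)
    return loglik, grad, info


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    drop_collinear: bool = True,
) -> CoxResults:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    Parameters
    ----------
    covariates : array-like (n, p) or DataFrame
        Constant columns are non-estimable; collinear columns are
        dropped with a record in ``dropped`` when *drop_collinear*.

    Notes
    -----
    Separation (e.g. all events in one level of a binary covariate)
    drives the MLE to infinity; such fits are flagged
    ``non_estimable`` and their Wald p-values are NaN.
    """
    times, events = _check_surv(times, events)
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != times.size:
            X = X.T
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if X.shape[0] != times.size:
        raise ValueError("covariate rows must match number of samples")

    dropped: list[str] = []
    keep = list(range(X.shape[1]))
    # constant columns can never be estimated
    const = [i for i in keep if np.ptp(X[:, i]) == 0]
    if const:
        dropped += [names[i] for i in const]
        keep = [i for i in keep if i not in const]
    if drop_collinear and len(keep) > 1:
        sub = X[:, keep] - X[:, keep].mean(axis=0)
        r = np.linalg.matrix_rank(sub)
        while r < len(keep):
            # drop trailing columns until full rank
            cand = keep[-1]
            dropped.append(names[cand])
            keep = keep[:-1]
            sub = X[:, keep] - X[:, keep].mean(axis=0)
            r = np.linalg.matrix_rank(sub)

    def _result(beta_k, bse_k, ll, conv, nonest, it, sstat, sp):
        params = np.full(len(names), np.nan)
        bse = np.full(len(names), np.nan)
        for slot, i in enumerate(keep):
            params[i] = beta_k[slot]
            bse[i] = bse_k[slot]
        return CoxResults(
            params, bse, names, times.size, int(events.sum()), ll,
            conv, nonest, it, sstat, sp, dropped,
        )

    if not keep:
        return _result(np.array([]), np.array([]), np.nan, False, True, 0,
                       np.nan, np.nan)

    Xk = X[:, keep]
    center = Xk.mean(axis=0)
    Xc = Xk - center
    p = Xc.shape[1]

    # score test at beta = 0
    ll0, g0, i0 = _efron_quantities(np.zeros(p), times, events, Xc)
    try:
        score_stat = float(g0 @ np.linalg.solve(i0, g0))
        score_p = float(stats.chi2.sf(score_stat, df=p))
    except np.linalg.LinAlgError:
        score_stat, score_p = np.nan, np.nan

    beta = np.zeros(p)
    converged = False
    non_estimable = False
    ll = ll0
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, info = _efron_quantities(beta, times, events, Xc)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            non_estimable = True
            break
        # step-halving to keep the likelihood non-decreasing
        new = beta + step
        for _ in range(20):
            ll_new = _efron_quantities(new, times, events, Xc)[0]
            if ll_new >= ll - 1e-12:
                break
            new = (beta + new) / 2.0
        beta = new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 15:
            non_estimable = True  # monotone likelihood / separation
            break
    if not converged and not non_estimable:
        non_estimable = True

    ll, grad, info = _efron_quantities(beta, times, events, Xc)
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        non_estimable = True
    return _result(beta, bse, ll, converged, non_estimable, it,
                   score_stat, score_p)


# ---------------------------------------------------------------- adjustments

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Output is monotone over the sorted order and bounded by [p, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# ----------------------------------------------------------- categorical tests

def fisher_or_chisq(table) -> dict:
    """2x2 association test with the expected-count rule.

    Fisher's exact test (two-sided, point-probability method) when any
    expected count is below 5 or any observed cell is zero (where the
    chi-squared approximation is unreliable), otherwise Pearson
    chi-squared without continuity correction.  The odds ratio uses a
    Haldane 0.5 correction when a zero cell occurs.  A zero margin
    yields p = 1 and no odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    t = np.round(t).astype(int)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return {"p": 1.0, "odds_ratio": np.nan, "test": "degenerate"}
    expected = np.outer(rows, cols) / n
    a, b, c, d = t.ravel()
    if (t == 0).any():
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    if (expected < 5).any() or (t == 0).any():
        p = float(stats.fisher_exact(t, alternative="two-sided")[1])
        test = "fisher"
    else:
        p = float(stats.chi2_contingency(t, correction=False)[1])
        test = "chi2"
    return {"p": p, "odds_ratio": float(orat), "test": test}


def wilcoxon_tests(x, y, paired: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) test.

    Exact null distribution is used for small tie-free samples, the
    tie-corrected normal approximation otherwise.  Returns
    (statistic, two-sided p).  All-tied paired data yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
        return float(res.statistic), float(res.pvalue)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------- methylation screens

def methylation_binarize(beta, threshold: float = 0.3):
    """Binarize methylation beta values: methylated iff beta >= threshold.

    The boundary value counts as methylated.  Returns a boolean (array)
    where True means methylated.
    """
    b = np.asarray(beta, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    out = b >= threshold
    return bool(out) if np.isscalar(beta) else out


def silencing_screen(
    expression: pd.DataFrame,
    beta: pd.DataFrame,
    min_abs_diff: float = 1.0,
    p_max: float = 0.05,
    beta_threshold: float = 0.3,
) -> pd.DataFrame:
    """Flag epigenetically silenced genes.

    For each gene, samples are split into methylated / unmethylated at
    *beta_threshold*; the gene is flagged silenced when the methylated
    group's mean expression is LOWER than the unmethylated group's, the
    absolute mean difference is at least *min_abs_diff*, and the
    Wilcoxon rank-sum p-value is below *p_max*.  Genes with an empty
    group are not evaluable.

    Both inputs are genes x samples with matching indices/columns.
    """
    genes = expression.index.intersection(beta.index)
    cols = expression.columns.intersection(beta.columns)
    rows = []
    for g in genes:
        e = expression.loc[g, cols].to_numpy(dtype=float)
        meth = methylation_binarize(beta.loc[g, cols].to_numpy(dtype=float),
                                    beta_threshold)
        n_m, n_u = int(meth.sum()), int((~meth).sum())
        if n_m == 0 or n_u == 0:
            rows.append((g, n_m, n_u, np.nan, np.nan, False, False))
            continue
        diff = float(e[~meth].mean() - e[meth].mean())  # unmeth - meth
        _, p = wilcoxon_tests(e[meth], e[~meth])
        silenced = diff >= min_abs_diff and p < p_max
        rows.append((g, n_m, n_u, diff, p, bool(silenced), True))
    return pd.DataFrame(
        rows,
        columns=["gene", "n_methylated", "n_unmethylated", "mean_diff",
                 "p", "silenced", "evaluable"],
    ).set_index("gene")
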