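"""De novo mutational-signature extraction by non-negative matrix factorization.

The catalog (channels x samples matrix V) is factorized as V ~ P E with
96 x r signature profiles P and r x n exposures E, using multiplicative
updates under the generalized Kullback-Leibler divergence (the Brunet
variant; a Frobenius objective is available behind a flag).  The
factorization rank is selected by the cophenetic correlation of the
restart-consensus matrix, with the residual sum of squares reported as
a secondary diagnostic.  Extracted profiles are annotated against a
reference signature table by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .catalog import MutationCatalog
from .channels import CHANNELS, N_CHANNELS

_EPS = np.finfo(float).tiny


# ------------------------------------------------------------------ utilities

def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two non-negative vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _kl_objective(V, WH):
    mask = V > 0
    return float(
        np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V[mask].sum() + WH.sum()
    )


def _kl_nmf(V, r, rng, max_iter, tol):
    """Lee-Seung multiplicative updates for generalized KL divergence."""
    m, n = V.shape
    scale = np.sqrt(V.mean() / r) if V.mean() > 0 else 1.0
    W = rng.uniform(0.5, 1.5, size=(m, r)) * scale
    H = rng.uniform(0.5, 1.5, size=(r, n)) * scale
    WH = W @ H + _EPS
    obj = _kl_objective(V, WH)
    trace = [obj]
    for it in range(max_iter):
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        WH = W @ H + _EPS
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            new = _kl_objective(V, WH)
            trace.append(new)
            if abs(trace[-2] - new) <= tol * max(abs(new), 1.0):
                break
    return W, H, trace


def _frobenius_nmf(V, r, rng, max_iter, tol):
    m, n = V.shape
    scale = np.sqrt(V.mean() / r) if V.mean() > 0 else 1.0
    W = rng.uniform(0.5, 1.5, size=(m, r)) * scale
    H = rng.uniform(0.5, 1.5, size=(r, n)) * scale
    obj = float(((V - W @ H) ** 2).sum())
    trace = [obj]
    for it in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            new = float(((V - W @ H) ** 2).sum())
            trace.append(new)
            if abs(trace[-2] - new) <= tol * max(abs(new), 1.0):
                break
    return W, H, trace


def _normalize_factors(W, H):
    """Column-normalize profiles, rescaling exposures to preserve W @ H."""
    col = W.sum(axis=0)
    col_safe = np.where(col > 0, col, 1.0)
    return W / col_safe, H * col[:, None]


# -------------------------------------------------------------------- results

@dataclass
class SignatureResults:
    """A fitted signature factorization.

    Attributes
    ----------
    profiles : DataFrame, 96 x r
        Signature profiles; each column sums to 1.
    exposures : DataFrame, r x n_samples
        Non-negative signature loadings; profiles @ exposures
        approximates the (channels x samples) catalog.
    """

    rank: int
    profiles: pd.DataFrame
    exposures: pd.DataFrame
    objective: float
    objective_trace: list[float]
    rss: float
    n_restarts: int
    seed: int | None
    objective_kind: str = "kl"

    @property
    def samples(self) -> list[str]:
        return list(self.exposures.columns)

    def exposure_fractions(self) -> pd.DataFrame:
        """Per-sample exposures normalized to sum 1 (zero columns stay zero)."""
        e = self.exposures.to_numpy()
        tot = e.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, e / tot, 0.0)
        return pd.DataFrame(frac, index=self.exposures.index,
                            columns=self.exposures.columns)

    def reconstruction(self) -> np.ndarray:
        return self.profiles.to_numpy() @ self.exposures.to_numpy()

    def annotate(self, reference: pd.DataFrame) -> pd.DataFrame:
        return annotate_signatures(self.profiles, reference)

    def summary(self) -> pd.DataFrame:
        frac = self.exposure_fractions().mean(axis=1)
        return pd.DataFrame(
            {
                "mean_exposure_fraction": frac,
                "top_channel": self.profiles.idxmax(axis=0),
                "top_channel_weight": self.profiles.max(axis=0),
            }
        )

    def plot_profiles(self, ax=None):
        import matplotlib.pyplot as plt

        r = self.rank
        fig, axes = plt.subplots(r, 1, figsize=(10, 1.6 * r), sharex=True)
        axes = np.atleast_1d(axes)
        for i, (name, col) in enumerate(self.profiles.items()):
            axes[i].bar(range(N_CHANNELS), col.to_numpy(), width=0.8)
            axes[i].set_ylabel(str(name), fontsize=7)
        axes[-1].set_xlabel("channel (COSMIC order)")
        return fig


def nmf_factorize(
    catalog: MutationCatalog | np.ndarray,
    r: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    objective: str = "kl",
    use_frequencies: bool = False,
) -> SignatureResults:
    """Best-of-restarts NMF of the mutation catalog at a fixed rank."""
    V, sample_names = _as_matrix(catalog, use_frequencies)
    _check_rank(r, V)
    best, _ = _fit_restarts(V, r, n_restarts, max_iter, tol, seed, objective)
    W, H, trace = best
    W, H = _normalize_factors(W, H)
    rss = float(((V - W @ H) ** 2).sum())
    return SignatureResults(
        rank=r,
        profiles=pd.DataFrame(W, index=pd.Index(CHANNELS, name="channel"),
                              columns=[f"S{i + 1}" for i in range(r)]),
        exposures=pd.DataFrame(H, index=[f"S{i + 1}" for i in range(r)],
                               columns=sample_names),
        objective=trace[-1],
        objective_trace=trace,
        rss=rss,
        n_restarts=n_restarts,
        seed=seed,
        objective_kind=objective,
    )


def _as_matrix(catalog, use_frequencies):
    if isinstance(catalog, MutationCatalog):
        M = catalog.frequencies() if use_frequencies else catalog.counts.astype(float)
        return M.T.copy(), list(catalog.samples)
    V = np.asarray(catalog, dtype=float)
    if V.shape[0] != N_CHANNELS:
        if V.shape[1] == N_CHANNELS:
            V = V.T
        else:
            raise ValueError("matrix must have 96 channels on one axis")
    return V.copy(), [f"sample{j}" for j in range(V.shape[1])]


def _check_rank(r, V):
    if r < 1:
        raise ValueError("rank must be >= 1")
    if r >= min(V.shape):
        raise ValueError(f"rank {r} >= min matrix dimension {min(V.shape)}")


def _fit_restarts(V, r, n_restarts, max_iter, tol, seed, objective):
    """Run restarts; return the best factorization and per-restart labels."""
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    fit = _kl_nmf if objective == "kl" else _frobenius_nmf
    ss = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    labels = []
    for child in ss:
        rng = np.random.default_rng(child)
        W, H, trace = fit(V, r, rng, max_iter, tol)
        labels.append(np.argmax(H, axis=0))
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    return best, labels


# -------------------------------------------------------------- rank selection

@dataclass
class RankSelection:
    """Cophenetic/RSS diagnostics over a rank range with the chosen rank."""

    metrics: pd.DataFrame  # index rank; columns cophenetic, rss, chosen
    chosen_rank: int
    results: dict[int, SignatureResults]

    @property
    def best(self) -> SignatureResults:
        return self.results[self.chosen_rank]

    def summary(self) -> pd.DataFrame:
        return self.metrics


def _cophenetic_rho(labels: list[np.ndarray]) -> float:
    """Cophenetic correlation of the restart co-assignment consensus."""
    n = labels[0].size
    C = np.zeros((n, n))
    for lab in labels:
        C += (lab[:, None] == lab[None, :]).astype(float)
    C /= len(labels)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.all(condensed == condensed[0]):
        return 1.0  # degenerate: all distances equal, perfectly consistent
    Z = average(condensed)
    rho, _ = cophenet(Z, condensed)
    return float(rho)


def rank_selection(
    catalog: MutationCatalog | np.ndarray,
    rank_range=range(2, 11),
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    objective: str = "kl",
    use_frequencies: bool = False,
) -> RankSelection:
    """Factorize at each candidate rank and select by cophenetic correlation.

    For each rank the restart hard assignments (argmax exposure) define
    a sample co-assignment consensus matrix; its cophenetic correlation
    under average linkage measures restart stability.  The chosen rank
    maximizes the cophenetic coefficient, ties broken toward the
    smaller rank; RSS of the best restart is reported alongside.
    """
    if n_restarts < 2:
        raise ValueError("cophenetic coefficient needs at least 2 restarts")
    V, sample_names = _as_matrix(catalog, use_frequencies)
    rows = []
    results = {}
    ss = np.random.SeedSequence(seed).spawn(len(list(rank_range)))
    for child, r in zip(ss, rank_range):
        _check_rank(r, V)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        best, labels = _fit_restarts(V, r, n_restarts, max_iter, tol,
                                     sub_seed, objective)
        W, H, trace = best
        Wn, Hn = _normalize_factors(W, H)
        rss = float(((V - Wn @ Hn) ** 2).sum())
        rho = _cophenetic_rho(labels)
        rows.append((r, rho, rss))
        results[r] = SignatureResults(
            rank=r,
            profiles=pd.DataFrame(Wn, index=pd.Index(CHANNELS, name="channel"),
                                  columns=[f"S{i + 1}" for i in range(r)]),
            exposures=pd.DataFrame(Hn, index=[f"S{i + 1}" for i in range(r)],
                                   columns=sample_names),
            objective=trace[-1],
            objective_trace=trace,
            rss=rss,
            n_restarts=n_restarts,
            seed=sub_seed,
            objective_kind=objective,
        )
    metrics = pd.DataFrame(rows, columns=["rank", "cophenetic", "rss"]).set_index("rank")
    chosen = int(metrics["cophenetic"].idxmax())  # idxmax takes first (smallest) on ties
    metrics["chosen"] = metrics.index == chosen
    return RankSelection(metrics, chosen, results)


# ------------------------------------------------------------------ annotation

def annotate_signatures(profiles: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Map each extracted profile to its nearest reference signature.

    Nearest by cosine similarity; ties broken toward the lower-numbered
    (earlier-column) reference signature.  Many-to-one mappings are
    allowed and flagged.
    """
    P = np.asarray(profiles, dtype=float)
    R = np.asarray(reference, dtype=float)
    if P.shape[0] != R.shape[0]:
        raise ValueError(
            f"profiles have {P.shape[0]} channels but reference has {R.shape[0]}"
        )
    ref_names = list(reference.columns)
    rows = []
    for j in range(P.shape[1]):
        sims = np.array([cosine_similarity(P[:, j], R[:, k])
                         for k in range(R.shape[1])])
        order = np.argsort(-sims, kind="stable")  # stable: ties -> earlier column
        best, second = order[0], order[1] if order.size > 1 else order[0]
        rows.append(
            {
                "extracted": profiles.columns[j] if hasattr(profiles, "columns") else j,
                "best_match": ref_names[best],
                "best_similarity": float(sims[best]),
                "runner_up": ref_names[second],
                "runner_up_similarity": float(sims[second]),
            }
        )
    out = pd.DataFrame(rows).set_index("extracted")
    dup = out["best_match"].duplicated(keep=False)
    out["many_to_one"] = dup
    return out


# ----------------------------------------------------------------- model class

class SignatureModel:
    """NMF signature model over a mutation catalog (statsmodels-style).

    >>> model = SignatureModel(catalog)
    >>> res = model.fit(rank=3, seed=0)       # SignatureResults
    >>> sel = model.select_rank(range(2, 7))  # RankSelection
    """

    def __init__(self, catalog: MutationCatalog | np.ndarray,
                 use_frequencies: bool = False, objective: str = "kl"):
        self.catalog = catalog
        self.use_frequencies = use_frequencies
        self.objective = objective

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SignatureModel":
        """Build from a samples x 96 DataFrame (channel-named columns)."""
        cat = MutationCatalog(list(df.index.astype(str)),
                              df[list(CHANNELS)].to_numpy())
        return cls(cat, **kwargs)

    def fit(self, rank: int, n_restarts: int = 30, max_iter: int = 2000,
            tol: float = 1e-6, seed: int | None = None) -> SignatureResults:
        return nmf_factorize(
            self.catalog, rank, n_restarts, max_iter, tol, seed,
            objective=self.objective, use_frequencies=self.use_frequencies,
        )

    def select_rank(self, rank_range=range(2, 11), n_restarts: int = 30,
                    max_iter: int = 2000, tol: float = 1e-6,
                    seed: int | None = None) -> RankSelection:
        return rank_selection(
            self.catalog, rank_range, n_restarts, max_iter, tol, seed,
            objective=self.objective, use_frequencies=self.use_frequencies,
        )
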