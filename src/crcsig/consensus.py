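"""Consensus clustering with PAC-based selection of the cluster number.

Samples are repeatedly subsampled (80% without replacement by default)
and partitioned by Euclidean k-means for each candidate k; the consensus
matrix entry (i, j) is the fraction of co-sampled iterations in which i
and j landed in the same cluster.  The number of clusters is chosen by
minimizing the proportion of ambiguous clustering (PAC), the mass of the
consensus CDF falling in an intermediate interval (default (0.1, 0.9]).
Final labels come from average-linkage hierarchical clustering of
1 - consensus, cut at the chosen k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans


def pac(consensus: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering of a consensus matrix.

    The fraction of defined lower-triangle entries in (u1, u2];
    undefined (never co-sampled, NaN) entries are excluded.
    """
    if not (0 <= u1 < u2 <= 1):
        raise ValueError("need 0 <= u1 < u2 <= 1")
    M = np.asarray(consensus, dtype=float)
    tri = M[np.tril_indices_from(M, k=-1)]
    tri = tri[~np.isnan(tri)]
    if tri.size == 0:
        raise ValueError("no defined consensus entries")
    return float(np.mean((tri > u1) & (tri <= u2)))


def consensus_cdf(consensus: np.ndarray, grid: np.ndarray | None = None):
    """Empirical CDF of the defined lower-triangle consensus entries."""
    M = np.asarray(consensus, dtype=float)
    tri = M[np.tril_indices_from(M, k=-1)]
    tri = tri[~np.isnan(tri)]
    if grid is None:
        grid = np.linspace(0, 1, 101)
    cdf = np.array([(tri <= g).mean() for g in grid])
    return grid, cdf


def final_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut average-linkage clustering of 1 - consensus into k clusters.

    Missing entries are imputed with the matrix mean; cluster ids are
    0-based and ordered by decreasing cluster size.
    """
    M = np.asarray(consensus, dtype=float).copy()
    n = M.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    nanmask = np.isnan(M)
    if nanmask.any():
        M[nanmask] = np.nanmean(M)
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = average(squareform(np.clip(D, 0, None), checks=False))
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order cluster ids by decreasing size, ties by first appearance
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[c]))
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


@dataclass
class ConsensusResults:
    """Per-k consensus matrices, PAC values, chosen k and final labels."""

    consensus: dict[int, np.ndarray]
    pac_values: pd.Series  # index k
    chosen_k: int
    labels: np.ndarray  # final labels at chosen_k, 0-based
    sample_names: list[str]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_names, "cluster": self.labels}
        ).set_index("sample_id")

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"PAC": self.pac_values})
        out["chosen"] = out.index == self.chosen_k
        return out

    def plot_consensus(self, k: int | None = None, ax=None):
        import matplotlib.pyplot as plt

        if k is None:
            k = self.chosen_k
        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(final_labels(self.consensus[k], k), kind="stable")
        ax.imshow(self.consensus[k][np.ix_(order, order)], vmin=0, vmax=1,
                  cmap="viridis")
        ax.set_title(f"consensus, k={k}")
        return ax


class ConsensusCluster:
    """Consensus k-means clustering model over a samples x features matrix.

    >>> model = ConsensusCluster(features)
    >>> res = model.fit(k_max=9, n_iter=1000, seed=0)
    >>> res.chosen_k, res.labels
    """

    def __init__(self, features, sample_names=None):
        if isinstance(features, pd.DataFrame):
            if sample_names is None:
                sample_names = list(features.index.astype(str))
            features = features.to_numpy(dtype=float)
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (samples x dims)")
        n = self.features.shape[0]
        self.sample_names = (
            list(sample_names) if sample_names is not None
            else [f"sample{i}" for i in range(n)]
        )

    def fit(
        self,
        k_max: int = 9,
        n_iter: int = 1000,
        subsample_fraction: float = 0.8,
        seed: int | None = None,
        n_init: int = 10,
        u1: float = 0.1,
        u2: float = 0.9,
    ) -> ConsensusResults:
        """Run the subsampled k-means consensus procedure for k = 2..k_max."""
        X = self.features
        n = X.shape[0]
        if n < 10:
            raise ValueError("need at least 10 samples")
        m = int(np.floor(subsample_fraction * n))
        if k_max >= m:
            raise ValueError(f"k_max={k_max} >= subsample size {m}")
        ks = range(2, k_max + 1)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        co_cluster = {k: np.zeros((n, n)) for k in ks}
        co_sample = np.zeros((n, n))

        for _ in range(n_iter):
            idx = rng.choice(n, size=m, replace=False)
            ind = np.zeros(n, dtype=bool)
            ind[idx] = True
            co_sample += np.outer(ind, ind)
            km_seed = int(rng.integers(0, 2**31 - 1))
            for k in ks:
                km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                            random_state=km_seed)
                lab = km.fit_predict(X[idx])
                for c in range(k):
                    members = idx[lab == c]
                    sel = np.zeros(n, dtype=bool)
                    sel[members] = True
                    co_cluster[k] += np.outer(sel, sel)

        consensus = {}
        pac_vals = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for k in ks:
                M = np.where(co_sample > 0, co_cluster[k] / co_sample, np.nan)
                np.fill_diagonal(M, 1.0)
                consensus[k] = M
                pac_vals[k] = pac(M, u1, u2)
        pac_series = pd.Series(pac_vals, name="PAC")
        chosen = int(pac_series.idxmin())  # first minimum -> smaller k on ties
        labels = final_labels(consensus[chosen], chosen)
        return ConsensusResults(consensus, pac_series, chosen, labels,
                                self.sample_names)


def consensus_cluster(
    features,
    k_max: int = 9,
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
    **kwargs,
) -> ConsensusResults:
    """Functional wrapper around :class:`ConsensusCluster`."""
    return ConsensusCluster(features).fit(
        k_max=k_max, n_iter=n_iter, subsample_fraction=subsample_fraction,
        seed=seed, **kwargs,
    )
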