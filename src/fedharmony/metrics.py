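"""Integration-quality metrics: iLISI, ARI, and the k-means ARI sweep.

iLISI (integration local inverse Simpson's index) measures, for each
cell, the effective number of batches represented among its nearest
neighbors: neighbor weights are Gaussian, with the bandwidth tuned per
cell so the weight distribution has a target perplexity, and the index is
the inverse Simpson's index of the weighted batch distribution. Values
lie in [1, B]: 1 means single-batch neighborhoods (strong batch effect),
B means perfect mixing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors


@dataclass
class LISIResult:
    values: np.ndarray
    median: float
    perplexity: float

    def to_csv(self, path, cell_ids=None) -> None:
        ids = cell_ids if cell_ids is not None else np.arange(len(self.values))
        pd.DataFrame({"cell_id": ids, "ilisi": self.values}).to_csv(path, index=False)


def _tune_weights(d2: np.ndarray, perplexity: float, n_iter: int = 64,
                  tol: float = 1e-5) -> np.ndarray:
    """Per-row Gaussian weights with entropy log(perplexity), via bisection on beta."""
    n, k = d2.shape
    log_target = np.log(perplexity)
    beta = np.ones(n)
    lo = np.full(n, -np.inf)
    hi = np.full(n, np.inf)
    P = np.empty_like(d2)
    for _ in range(n_iter):
        np.exp(-d2 * beta[:, None], out=P)
        sumP = P.sum(axis=1)
        zero = sumP <= 0
        if np.any(zero):  # bandwidth collapsed; fall back to uniform for those rows
            P[zero] = 1.0
            sumP[zero] = k
        H = np.log(sumP) + beta * (d2 * P).sum(axis=1) / sumP
        P /= sumP[:, None]
        diff = H - log_target
        if np.all(np.abs(diff) < tol):
            break
        too_entropic = diff > 0
        lo = np.where(too_entropic, beta, lo)
        hi = np.where(~too_entropic, beta, hi)
        beta = np.where(
            too_entropic,
            np.where(np.isfinite(hi), (beta + hi) / 2.0, beta * 2.0),
            np.where(np.isfinite(lo), (beta + lo) / 2.0, beta / 2.0),
        )
    return P


def ilisi(embedding: np.ndarray, batch_labels, perplexity: float = 30.0) -> LISIResult:
    """Per-cell integration LISI over a d x N embedding.

    Uses 3*perplexity nearest neighbors (the convention of the original
    LISI implementation); requires N > 3*perplexity.
    """
    Z = np.asarray(embedding, dtype=float)
    labels = np.asarray(batch_labels)
    d, N = Z.shape
    if labels.shape[0] != N:
        raise ValueError("one batch label per cell required")
    n_neighbors = int(round(3 * perplexity))
    if N <= n_neighbors:
        raise ValueError(f"need N > 3*perplexity (= {n_neighbors}) cells, got {N}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z.T)
    dist, idx = nn.kneighbors(Z.T)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    P = _tune_weights(dist**2, perplexity)
    cats, codes = np.unique(labels, return_inverse=True)
    B = len(cats)
    batch_probs = np.zeros((N, B))
    neigh_codes = codes[idx]
    for b in range(B):
        batch_probs[:, b] = np.where(neigh_codes == b, P, 0.0).sum(axis=1)
    simpson = (batch_probs**2).sum(axis=1)
    values = 1.0 / np.maximum(simpson, 1.0 / B)  # clip into [1, B]
    values = np.minimum(values, B)
    return LISIResult(values=values, median=float(np.median(values)),
                      perplexity=perplexity)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same cells."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))


def kmeans_ari_sweep(emb_a: np.ndarray, emb_b: np.ndarray, k_range, seed: int = 0,
                     n_restarts: int = 10) -> pd.DataFrame:
    """Seeded k-means on both embeddings for each k; ARI between the labelings.

    Embeddings are d x N and must be aligned cell-for-cell. Each k-means
    uses ``n_restarts`` initializations, keeping the best-inertia
    labeling.
    """
    A, Bm = np.asarray(emb_a), np.asarray(emb_b)
    if A.shape[1] != Bm.shape[1]:
        raise ValueError("embeddings must cover the same cells")
    N = A.shape[1]
    rows = []
    for k in k_range:
        if k > N:
            raise ValueError(f"k={k} exceeds the number of cells {N}")
        la = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**31)).fit_predict(A.T)
        lb = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**31)).fit_predict(Bm.T)
        rows.append({"k": k, "ari": ari(la, lb)})
    return pd.DataFrame(rows)
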