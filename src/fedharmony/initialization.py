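"""Federated initialization: k-means centroids, local R, and the O/E bookkeeping.

Order of operations: federated k-means -> broadcast Y -> each site
initializes its local soft assignments (penalty-free softmax) -> sites
send per-cluster row sums -> server assembles O, Pr_b and E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import _kernels as kern
from .federation import SERVER, Message, MessageBus, SiteHandle


@dataclass(frozen=True)
class PhiBookkeeping:
    """Block-structured batch indicator, materialized lazily.

    With cells ordered by site, phi is B x N with row b carrying ones over
    site b's contiguous column range. The dense matrix is only ever built
    for oracle comparisons, never placed in a message.
    """

    cell_counts: tuple[int, ...]

    @property
    def B(self) -> int:
        return len(self.cell_counts)

    @property
    def N(self) -> int:
        return sum(self.cell_counts)

    @property
    def Pr_b(self) -> np.ndarray:
        counts = np.asarray(self.cell_counts, dtype=float)
        return counts / counts.sum()

    def phi_site(self, b: int) -> np.ndarray:
        """The B x N_b slab for site b: row b all ones."""
        slab = np.zeros((self.B, self.cell_counts[b]))
        slab[b, :] = 1.0
        return slab

    def dense(self) -> np.ndarray:
        """Full B x N one-hot matrix (oracle/testing use only)."""
        return np.concatenate([self.phi_site(b) for b in range(self.B)], axis=1)


def build_phi_bookkeeping(cell_counts) -> PhiBookkeeping:
    counts = tuple(int(c) for c in cell_counts)
    if any(c < 1 for c in counts):
        raise ValueError("every site must contribute at least one cell")
    return PhiBookkeeping(counts)


def _weighted_kmeans_plusplus(
    X: np.ndarray, weights: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding over weighted candidate points (rows of X)."""
    w = np.clip(weights.astype(float), 0.0, None)
    if not np.any(w > 0):
        w = np.ones(len(X))
    probs = w / w.sum()
    centers = [X[rng.choice(len(X), p=probs)]]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for _ in range(1, K):
        scores = w * d2
        total = scores.sum()
        if total <= 0:  # all remaining mass sits on chosen points
            idx = rng.choice(len(X), p=probs)
        else:
            idx = rng.choice(len(X), p=scores / total)
        centers.append(X[idx])
        d2 = np.minimum(d2, np.sum((X - centers[-1]) ** 2, axis=1))
    return np.asarray(centers)


def federated_kmeans(
    sites: list[SiteHandle],
    K: int,
    seed: int,
    bus: MessageBus | None = None,
    max_rounds: int = 25,
    tol: float = 1e-9,
) -> np.ndarray:
    """Aggregated-Lloyd k-means over the sites' normalized embeddings.

    Each site proposes local k-means centroids with occupancy counts
    (cluster-level aggregates, padded to K columns when a site has fewer
    candidates). The server seeds K centroids by weighted k-means++ over
    the pooled candidates, then iterates Lloyd rounds in which sites send
    per-centroid coordinate sums and counts. Returns Y (d x K) with
    L2-normalized columns.
    """
    d = sites[0].Z_cos.shape[0]
    N_total = sum(s.n_cells for s in sites)
    if K > N_total:
        raise ValueError(f"K={K} exceeds the total cell count {N_total}")

    cand_pts, cand_wts = [], []
    for site in sites:
        n_local = min(K, site.n_cells)
        km = KMeans(
            n_clusters=n_local,
            n_init=1,
            max_iter=10,
            random_state=(seed + kern.KMEANS_STREAM + site.b) % (2**31),
        ).fit(site.Z_cos.T)
        centroids = np.zeros((d, K))
        counts = np.zeros(K)
        centroids[:, :n_local] = km.cluster_centers_.T
        counts[:n_local] = np.bincount(km.labels_, minlength=n_local)
        if bus is not None:
            bus.send(Message(f"site{site.b}", "local_centroid_sum",
                             {"candidates": centroids, "counts": counts}))
        cand_pts.append(centroids.T)
        cand_wts.append(counts)
    X = np.concatenate(cand_pts, axis=0)
    w = np.concatenate(cand_wts)
    rng = np.random.default_rng([seed, kern.KMEANS_STREAM])
    Y = _weighted_kmeans_plusplus(X, w, K, rng).T  # d x K

    for _ in range(max_rounds):
        if bus is not None:
            bus.next_round()  # one Lloyd step = one communication round
            bus.send(Message(SERVER, "global_centroids", {"Y": Y}))
        sums = np.zeros((d, K))
        counts = np.zeros(K)
        for site in sites:
            d2 = -2.0 * (Y.T @ site.Z_cos) + np.sum(Y * Y, axis=0)[:, None]
            labels = np.argmin(d2, axis=0)
            local_sums = np.zeros((d, K))
            np.add.at(local_sums.T, labels, site.Z_cos.T)
            local_counts = np.bincount(labels, minlength=K).astype(float)
            if bus is not None:
                bus.send(Message(f"site{site.b}", "local_centroid_sum",
                                 {"sums": local_sums, "counts": local_counts}))
            sums += local_sums
            counts += local_counts
        new_Y = np.where(counts > 0, sums / np.maximum(counts, 1.0), Y)
        shift = np.max(np.abs(new_Y - Y))
        Y = new_Y
        if shift < tol:
            break
    return kern.l2_normalize_columns(Y)


def init_R_site(Z_b: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Local penalty-free soft assignments from the broadcast centroids."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return kern.soft_assign_columns(Y, Z_b, sigma)


def init_O_E(
    r_rowsums: list[np.ndarray], cell_counts
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble O, E and the batch frequencies from per-site row sums.

    O[:, b] is site b's per-cluster soft mass; E = rowsum(O) Pr_b^T.
    """
    counts = np.asarray(cell_counts, dtype=float)
    if len(r_rowsums) != len(counts):
        raise ValueError("one row-sum vector per site required")
    K = len(r_rowsums[0])
    if any(len(v) != K for v in r_rowsums):
        raise ValueError("row-sum vectors must share length K")
    O = np.column_stack(r_rowsums)
    Pr_b = counts / counts.sum()
    E = np.outer(O.sum(axis=1), Pr_b)
    return O, E, Pr_b
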