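"""Per-site normalization, feature intersection, and aggregated-moment PCA.

The PCA here is an exact covariance-aggregation scheme: sites send only
their feature sums, second-moment matrix and cell count; the server
assembles the pooled mean and covariance, eigendecomposes once and
broadcasts the loadings, and every site projects its own cells locally.
By construction the result equals pooled PCA on the concatenated data up
to component sign. The G x G second-moment exchange is coarser than
per-cell data but richer than cluster aggregates (it sits between the
embedding and aggregate privacy tiers); pipelines that cannot accept it
can supply externally computed embeddings instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .federation import Message, MessageBus, SERVER


class EmptyIntersectionError(ValueError):
    """No feature is shared by all sites."""


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered feature identifiers shared by every site."""

    names: tuple[str, ...]

    def __post_init__(self):
        if not self.names:
            raise ValueError("feature space must be non-empty")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class PCAModel:
    """Pooled mean/scale and loadings broadcast to the sites."""

    mean: np.ndarray                # length G
    scale: np.ndarray               # length G (ones when scaling is off)
    loadings: np.ndarray            # G x d, column-orthonormal
    explained_variance: np.ndarray  # length d, nonincreasing

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project a G x n matrix into the d x n embedding."""
        return self.loadings.T @ ((X - self.mean[:, None]) / self.scale[:, None])

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, scale=self.scale, loadings=self.loadings,
                 explained_variance=self.explained_variance)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with np.load(path) as f:
            return cls(f["mean"], f["scale"], f["loadings"], f["explained_variance"])


def log_normalize(counts: np.ndarray, scale_factor: float = 1e4) -> np.ndarray:
    """Library-size normalization followed by log1p.

    Column j is scaled to total ``scale_factor``, then x -> ln(1 + x).
    All-zero columns map to all-zero columns.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = counts.sum(axis=0)
    if not np.any(totals > 0):
        raise ValueError("at least one cell must have nonzero counts")
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts * (scale_factor / safe))


def intersect_features(feature_lists: list[list[str]]) -> FeatureSpace:
    """Sorted intersection of per-site feature identifier lists."""
    if not feature_lists:
        raise ValueError("at least one site required")
    sets = [set(lst) for lst in feature_lists]
    common = set.intersection(*sets)
    if not common:
        report = "; ".join(
            f"site{b}: {len(s)} features, {len(s & set.union(*(sets[:b] + sets[b + 1:])) ) if len(sets) > 1 else 0} shared with others"
            for b, s in enumerate(sets)
        )
        raise EmptyIntersectionError(f"no feature shared by all sites ({report})")
    return FeatureSpace(tuple(sorted(common)))


def pooled_dispersion_ranking(site_matrices: list[np.ndarray]) -> np.ndarray:
    """Feature indices ranked by pooled variance (descending), from aggregated moments."""
    G = site_matrices[0].shape[0]
    s = np.zeros(G)
    ss = np.zeros(G)
    N = 0
    for X in site_matrices:
        s += X.sum(axis=1)
        ss += (X * X).sum(axis=1)
        N += X.shape[1]
    var = (ss - s * s / N) / max(N - 1, 1)
    return np.argsort(-var, kind="stable")


def select_hvg(site_matrices: list[np.ndarray], n_top: int = 2000) -> np.ndarray:
    """Top ``n_top`` features by pooled dispersion, as sorted indices."""
    ranking = pooled_dispersion_ranking(site_matrices)
    return np.sort(ranking[: min(n_top, len(ranking))])


def federated_pca(
    site_matrices: list[np.ndarray],
    d: int,
    scale: bool = True,
    bus: MessageBus | None = None,
    max_features: int = 4096,
) -> tuple[PCAModel, list[np.ndarray]]:
    """Exact pooled PCA from per-site first/second moments.

    Sites contribute (sum_j x_j, sum_j x_j x_j^T, N_b); the server forms
    the pooled covariance (optionally rescaled to unit pooled variance),
    takes the top-``d`` eigenvectors with a deterministic sign convention
    (largest-magnitude loading positive), and each site projects locally.
    Returns the model and the per-site d x N_b embeddings.
    """
    G = site_matrices[0].shape[0]
    if any(X.shape[0] != G for X in site_matrices):
        raise ValueError("all sites must share the feature space")
    if G > max_features:
        raise ValueError(
            f"G={G} features would require a {G}x{G} moment exchange; "
            "subset to shared highly variable features first (intersect_features/select_hvg)"
        )
    if d > G:
        raise ValueError("d must not exceed the number of features")
    N = sum(X.shape[1] for X in site_matrices)
    if N <= d:
        raise ValueError("need more cells than components")

    s = np.zeros(G)
    SS = np.zeros((G, G))
    for b, X in enumerate(site_matrices):
        s_b = X.sum(axis=1)
        SS_b = X @ X.T
        if bus is not None:
            bus.send(Message(f"site{b}", "site_moments_pca",
                             {"sum": s_b, "sum_outer": SS_b,
                              "n_cells": np.float64(X.shape[1])}))
        s += s_b
        SS += SS_b
    mean = s / N
    cov = (SS - N * np.outer(mean, mean)) / (N - 1)
    if scale:
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        sd = np.where(sd > 0, sd, 1.0)
        cov = cov / np.outer(sd, sd)
    else:
        sd = np.ones(G)
    vals, vecs = scipy.linalg.eigh(cov, subset_by_index=[G - d, G - 1])
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    flips = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(d)])
    vecs = vecs * np.where(flips == 0, 1.0, flips)
    model = PCAModel(mean, sd, vecs, vals)
    Z_sites = [model.project(X) for X in site_matrices]
    return model, Z_sites
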