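"""Shared numerical kernels for the centralized and federated paths.

Both code paths import from here so that, wherever the algorithm is
algebraically identical, the floating-point computation is identical too
(up to BLAS reduction order on differently shaped operands).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import xlogy

# RNG stream tag for block partitioning; keeps block draws decorrelated
# from other uses of the same seed.
BLOCK_STREAM = 101
KMEANS_STREAM = 202


def l2_normalize_columns(M: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Scale every column of ``M`` to unit Euclidean norm."""
    norms = np.linalg.norm(M, axis=0)
    return M / np.maximum(norms, eps)


def cosine_sq_dist(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance 2(1 - Y^T Z) between unit-norm columns.

    Returns a K x n matrix for Y (d x K) and Z (d x n).
    """
    return 2.0 * (1.0 - Y.T @ Z)


def diversity_log_penalty(O: np.ndarray, E: np.ndarray) -> np.ndarray:
    """log((O+1)/(E+1)) per (cluster, batch); +1 smoothing avoids log 0."""
    return np.log((O + 1.0) / (E + 1.0))


def soft_assign_columns(
    Y: np.ndarray,
    Z: np.ndarray,
    sigma: float,
    theta: float = 0.0,
    log_pen_cols: np.ndarray | None = None,
) -> np.ndarray:
    """Column-wise soft cluster assignment.

    R[:, i] is proportional to exp(-2(1 - Y_k^T Z_i)/sigma - Omega_ki)
    with the diversity penalty Omega_ki = theta * log((O+1)/(E+1)) for
    the column's batch, i.e. ((E+1)/(O+1))^theta * exp(-dist/sigma):
    cells are pushed away from clusters where their batch is
    over-represented. Evaluated via a numerically stable column softmax.
    ``log_pen_cols`` carries log((O+1)/(E+1)) per column (K x n, or K x 1
    broadcast); pass None for the penalty-free form used at
    initialization.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive for soft assignment (division by sigma)")
    logits = -cosine_sq_dist(Y, Z) / sigma
    if log_pen_cols is not None and theta != 0.0:
        logits = logits - theta * log_pen_cols
    logits -= logits.max(axis=0, keepdims=True)
    W = np.exp(logits)
    return W / W.sum(axis=0, keepdims=True)


def objective_terms(
    R: np.ndarray,
    dist: np.ndarray,
    log_pen_cols: np.ndarray,
    sigma: float,
    theta: float,
) -> np.ndarray:
    """The three objective summands (distance, entropy, diversity) as scalars.

    ``log_pen_cols`` must already be expanded per cell (K x n).
    """
    d = float(np.sum(R * dist))
    ent = sigma * float(xlogy(R, R).sum())
    div = sigma * theta * float(np.sum(R * log_pen_cols))
    return np.array([d, ent, div])


def random_blocks(n: int, alpha: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into ceil(1/alpha) nearly equal blocks."""
    n_blocks = min(n, max(1, math.ceil(1.0 / alpha)))
    perm = rng.permutation(n)
    return [blk for blk in np.array_split(perm, n_blocks) if blk.size]


def block_rng(seed: int, outer_round: int, inner_iter: int, site: int) -> np.random.Generator:
    """Deterministic per-(round, iteration, site) generator for block draws.

    The centralized reference uses site index 0 for the pooled data, so a
    single-site federated run draws byte-identical blocks.
    """
    return np.random.default_rng([seed, BLOCK_STREAM, outer_round, inner_iter, site])
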