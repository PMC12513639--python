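"""Centralized Harmony: the pooled-data reference implementation.

This module implements the classic Harmony iteration — maximum-diversity
soft clustering alternating with a per-cluster mixture-of-experts linear
batch correction — on data pooled at a single machine. It serves as the
correctness oracle for the federated path: given identical inputs,
hyperparameters, initial centroids and block draws, the federated
implementation must reproduce these results.

Notation (columns are cells throughout):

* ``Z``      d x N embedding (PCA scores), L2-normalized columns for clustering
* ``phi``    B x N one-hot batch indicator
* ``R``      K x N soft cluster assignments, columns sum to 1
* ``Y``      d x K cluster centroids, unit columns
* ``O``      K x B observed cluster/batch co-occurrence, O = R phi^T
* ``E``      K x B expected co-occurrence under independence, E = rowsum(O) Pr_b^T
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import _kernels as kern
from .config import Hyperparameters


@dataclass
class HarmonyState:
    """Full pooled-data state of one Harmony run."""

    Z_orig: np.ndarray  # d x N input embedding; never modified
    Z_cos: np.ndarray   # d x N column-normalized working embedding
    phi: np.ndarray     # B x N
    R: np.ndarray       # K x N
    Y: np.ndarray       # d x K
    O: np.ndarray       # K x B
    E: np.ndarray       # K x B
    Pr_b: np.ndarray    # length B

    def validate(self, atol: float = 1e-8) -> None:
        """Raise if the bookkeeping invariants are violated."""
        if np.any(self.R < -atol):
            raise ValueError("R has negative entries")
        if not np.allclose(self.R.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("R columns must sum to 1")
        if not np.allclose(self.O, self.R @ self.phi.T, atol=atol):
            raise ValueError("O != R phi^T")
        if not np.allclose(self.E.sum(axis=1), self.O.sum(axis=1), atol=atol):
            raise ValueError("E row-sums must equal O row-sums")
        if not np.isclose(self.Pr_b.sum(), 1.0):
            raise ValueError("batch frequencies must sum to 1")


@dataclass
class HarmonyResult:
    Z_corr: np.ndarray           # d x N corrected embedding (input scale)
    Z_cos: np.ndarray            # d x N normalized corrected embedding
    state: HarmonyState
    objective_trace: list[list[float]] = field(default_factory=list)
    n_rounds: int = 0
    converged: bool = False


def objective(state: HarmonyState, hp: Hyperparameters) -> float:
    """Diversity-clustering objective.

    Sum over cells i and clusters k of
    ``R_ki * 2(1 - Y_k^T Z_i) + sigma R_ki log R_ki
    + sigma theta R_ki log((O+1)/(E+1))_{k, batch(i)}``,
    with the 0*log 0 := 0 convention.
    """
    for arr in (state.R, state.Y, state.Z_cos, state.O, state.E):
        if not np.all(np.isfinite(arr)):
            raise ValueError("nonfinite entries in state")
    dist = kern.cosine_sq_dist(state.Y, state.Z_cos)
    log_pen = kern.diversity_log_penalty(state.O, state.E) @ state.phi  # K x N
    return float(kern.objective_terms(state.R, dist, log_pen, hp.sigma, hp.theta).sum())


def update_R(state: HarmonyState, hp: Hyperparameters, block: np.ndarray) -> HarmonyState:
    """Block update of the soft assignments (in place).

    The block's contributions are removed from O and E, its columns of R
    recomputed from the diversity-penalized softmax, and the new
    contributions added back, so O = R phi^T stays exact.
    """
    if hp.sigma <= 0:
        raise ValueError("sigma must be positive (the update divides by sigma)")
    block = np.asarray(block, dtype=np.intp)
    if block.size == 0:
        raise ValueError("empty block")
    phi_blk = state.phi[:, block]
    R_blk = state.R[:, block]
    state.O -= R_blk @ phi_blk.T
    state.E -= np.outer(R_blk.sum(axis=1), state.Pr_b)
    log_pen_cols = kern.diversity_log_penalty(state.O, state.E) @ phi_blk
    state.R[:, block] = kern.soft_assign_columns(
        state.Y, state.Z_cos[:, block], hp.sigma, hp.theta, log_pen_cols
    )
    R_new = state.R[:, block]
    state.O += R_new @ phi_blk.T
    state.E += np.outer(R_new.sum(axis=1), state.Pr_b)
    return state


def compute_W(
    Z: np.ndarray,
    R_k: np.ndarray,
    phi: np.ndarray,
    lamb: float,
    ridge_intercept: bool = False,
) -> np.ndarray:
    """Per-cluster mixture-of-experts ridge solve.

    Returns W_k of shape (B+1) x d solving
    ``(phi* diag(R_k) phi*^T + Lambda) W_k = phi* diag(R_k) Z^T`` with
    ``phi*`` the batch indicator with an all-ones intercept row prepended
    and ``Lambda = lamb * I`` except a zero in the intercept slot (unless
    ``ridge_intercept``). The intercept row of the solution is zeroed so
    the correction removes only batch-dependent terms.
    """
    B, N = phi.shape
    if not np.any(R_k):
        return np.zeros((B + 1, Z.shape[0]))
    phi_star = np.vstack([np.ones((1, N)), phi])
    PR = phi_star * R_k
    S = PR @ phi_star.T
    T = PR @ Z.T
    Lam = lamb * np.eye(B + 1)
    if not ridge_intercept:
        Lam[0, 0] = 0.0
    try:
        W = np.linalg.solve(S + Lam, T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixture-of-experts system (empty batch with lamb=0?); "
            "use lamb > 0"
        ) from exc
    W[0, :] = 0.0
    return W


def correct(
    Z: np.ndarray,
    R: np.ndarray,
    phi: np.ndarray,
    W_list: list[np.ndarray],
) -> np.ndarray:
    """Apply the mixture-of-experts correction: Z - sum_k W_k^T phi* diag(R_k)."""
    B, N = phi.shape
    d = Z.shape[0]
    if R.shape[1] != N or len(W_list) != R.shape[0]:
        raise ValueError("shape mismatch between Z, R, phi and W")
    phi_star = np.vstack([np.ones((1, N)), phi])
    Z_hat = Z.copy()
    for k, W_k in enumerate(W_list):
        if W_k.shape != (B + 1, d):
            raise ValueError(f"W[{k}] has shape {W_k.shape}, expected {(B + 1, d)}")
        if np.any(W_k[0, :] != 0.0):
            raise ValueError("intercept row of every W_k must be zero before correction")
        Z_hat -= W_k.T @ (phi_star * R[k])
    return Z_hat


def initialize_state(
    Z: np.ndarray,
    phi: np.ndarray,
    hp: Hyperparameters,
    init_Y: np.ndarray | None = None,
) -> HarmonyState:
    """Seeded k-means++ centroids, penalty-free R, and the O/E bookkeeping."""
    d, N = Z.shape
    K = hp.resolve_k(N)
    Z_cos = kern.l2_normalize_columns(Z)
    if init_Y is None:
        km = KMeans(
            n_clusters=K,
            init="k-means++",
            n_init=10,
            max_iter=25,
            random_state=hp.seed % (2**31),
        ).fit(Z_cos.T)
        Y = km.cluster_centers_.T
    else:
        Y = np.asarray(init_Y, dtype=float)
    Y = kern.l2_normalize_columns(Y)
    R = kern.soft_assign_columns(Y, Z_cos, hp.sigma)
    Pr_b = phi.sum(axis=1) / N
    O = R @ phi.T
    E = np.outer(O.sum(axis=1), Pr_b)
    return HarmonyState(Z.copy(), Z_cos, phi, R, Y, O, E, Pr_b)


def _cluster_phase(state: HarmonyState, hp: Hyperparameters, outer_round: int) -> list[float]:
    """Inner clustering loop: Y update then random-block R updates."""
    N = state.Z_cos.shape[1]
    trace: list[float] = []
    for it in range(hp.max_inner_iterations):
        state.Y = kern.l2_normalize_columns(state.Z_cos @ state.R.T)
        rng = kern.block_rng(hp.seed, outer_round, it, 0)
        for block in kern.random_blocks(N, hp.block_fraction, rng):
            update_R(state, hp, block)
        trace.append(objective(state, hp))
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < hp.tol * abs(trace[-2]):
            break
    return trace


def run_harmony(
    Z: np.ndarray,
    phi: np.ndarray,
    hp: Hyperparameters,
    init_Y: np.ndarray | None = None,
) -> HarmonyResult:
    """Full centralized run: alternate clustering and correction to convergence."""
    state = initialize_state(Z, phi, hp, init_Y=init_Y)
    K = state.R.shape[0]
    traces: list[list[float]] = []
    Z_corr = state.Z_orig.copy()
    prev_obj: float | None = None
    converged = False
    n_rounds = 0
    for rnd in range(hp.max_rounds):
        n_rounds = rnd + 1
        traces.append(_cluster_phase(state, hp, rnd))
        W_list = [
            compute_W(state.Z_orig, state.R[k], phi, hp.lamb, hp.ridge_intercept)
            for k in range(K)
        ]
        Z_corr = correct(state.Z_orig, state.R, phi, W_list)
        state.Z_cos = kern.l2_normalize_columns(Z_corr)
        cur = traces[-1][-1]
        if prev_obj is not None and abs(prev_obj - cur) < hp.tol * abs(prev_obj):
            converged = True
            break
        prev_obj = cur
    return HarmonyResult(Z_corr, state.Z_cos, state, traces, n_rounds, converged)
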