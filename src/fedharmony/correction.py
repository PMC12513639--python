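"""Federated mixture-of-experts correction.

The per-cluster ridge system that Harmony solves on pooled data
decomposes exactly into per-site moments: each site computes, for every
cluster k,

    T_k(b) = phi_b* diag(R_k(b)) Z(b)^T        ((B+1) x d)
    S_k(b) = phi_b* diag(R_k(b)) phi_b*^T      ((B+1) x (B+1))

where phi_b* stacks an all-ones intercept row on the site's batch
indicator slab. The server aggregates the sums over sites, solves the
ridge system per cluster, zeroes the intercept row of every W_k *before*
broadcasting (so sites never see batch-independent terms), and each site
applies its own batch's correction rows locally. These are exact
algebraic identities, not approximations: given identical R, Z and
lambda, this path reproduces the centralized solve to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .federation import SERVER, Message, MessageBus, SiteHandle


@dataclass
class SiteMoments:
    """One site's per-cluster correction moments (cluster-level aggregates)."""

    b: int
    T: np.ndarray  # K x (B+1) x d
    S: np.ndarray  # K x (B+1) x (B+1)


def compute_site_moments(site: SiteHandle, B: int, bus: MessageBus | None = None) -> SiteMoments:
    """Local moments T_k(b), S_k(b) for all clusters.

    Only rows/columns {0, 1+b} of S_k(b) can be nonzero, and T_k(b) has
    identical intercept and own-batch rows, because the site's indicator
    slab has ones exactly in those rows. The wire payload is therefore
    the compact pair (d x K weighted coordinate sums, K soft masses) —
    K(d+1) floats, independent of the site's cell count — from which the
    dense moments are reconstructed.
    """
    if site.R is None:
        raise ValueError(f"site {site.b} has no soft assignments")
    K = site.R.shape[0]
    d = site.Z_orig.shape[0]
    M = site.Z_orig @ site.R.T        # d x K: per-cluster weighted coordinate sums
    s = site.R.sum(axis=1)            # K: per-cluster soft mass
    T = np.zeros((K, B + 1, d))
    S = np.zeros((K, B + 1, B + 1))
    row = 1 + site.b
    T[:, 0, :] = M.T
    T[:, row, :] = M.T
    S[:, 0, 0] = s
    S[:, 0, row] = s
    S[:, row, 0] = s
    S[:, row, row] = s
    if bus is not None:
        bus.send(Message(f"site{site.b}", "moments_TS",
                         {"weighted_sums": M, "soft_masses": s}))
    return SiteMoments(site.b, T, S)


def solve_W(
    S_sum: np.ndarray,
    T_sum: np.ndarray,
    lamb: float,
    ridge_intercept: bool = False,
) -> np.ndarray:
    """Server-side ridge solve from aggregated moments.

    Returns W of shape K x (B+1) x d with every intercept row zeroed.
    """
    K, Bp1, d = T_sum.shape
    Lam = lamb * np.eye(Bp1)
    if not ridge_intercept:
        Lam[0, 0] = 0.0
    W = np.zeros((K, Bp1, d))
    for k in range(K):
        if not np.any(T_sum[k]):
            continue
        try:
            W[k] = np.linalg.solve(S_sum[k] + Lam, T_sum[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular correction system for cluster {k}; use lamb > 0"
            ) from exc
    W[:, 0, :] = 0.0
    return W


def correct_site(site: SiteHandle, W: np.ndarray) -> np.ndarray:
    """Apply the broadcast correction locally: Z(b) - sum_k W_k^T phi_b* diag(R_k(b)).

    With the intercept rows already zeroed, the correction for cell i is
    sum_k R_ki * W_k[1+b, :] — a single matrix product, no inversion.
    """
    K, Bp1, d = W.shape
    if site.R is None or site.R.shape[0] != K:
        raise ValueError("site assignments missing or inconsistent with W")
    if site.Z_orig.shape[0] != d:
        raise ValueError(f"W has d={d} but site embedding has d={site.Z_orig.shape[0]}")
    if np.any(W[:, 0, :] != 0.0):
        raise ValueError("W must be finalized (intercept rows zeroed) before correction")
    rows = W[:, 0, :] + W[:, 1 + site.b, :]   # K x d (intercept rows are zero)
    return site.Z_orig - rows.T @ site.R
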