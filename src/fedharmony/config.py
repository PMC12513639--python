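"""Hyperparameters shared by the centralized and federated integration paths."""

from __future__ import annotations

from dataclasses import dataclass


def default_n_clusters(n_cells: int) -> int:
    """Default cluster count: min(100, N/30), at least 1."""
    return max(1, min(100, n_cells // 30))


@dataclass(frozen=True)
class Hyperparameters:
    """Tuning knobs of the diversity-clustering / mixture-of-experts loop.

    Parameters
    ----------
    sigma
        Entropy weight of the soft clustering. Smaller values make
        assignments harder; 0 is allowed only when evaluating the
        objective (the k-means limit), not for R updates.
    theta
        Diversity weight. 0 disables the batch-diversity penalty.
    lamb
        Ridge penalty on the per-batch rows of each correction factor.
    n_clusters
        Number of soft clusters K. ``None`` resolves to
        ``min(100, N // 30)`` at run time.
    block_fraction
        Fraction alpha of cells updated per block during clustering.
    tol
        Relative objective-change threshold for convergence (both the
        inner clustering loop and the outer correction loop).
    max_rounds
        Cap on outer clustering/correction rounds.
    max_inner_iterations
        Cap on clustering iterations within one round.
    seed
        Seed for k-means initialization and block partitioning.
    ridge_intercept
        If True, penalize the intercept row too (the literal lambda*I
        ridge); default leaves the intercept unpenalized.
    """

    sigma: float = 0.1
    theta: float = 2.0
    lamb: float = 1.0
    n_clusters: int | None = None
    block_fraction: float = 0.05
    tol: float = 1e-4
    max_rounds: int = 10
    max_inner_iterations: int = 20
    seed: int = 0
    ridge_intercept: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if self.lamb < 0:
            raise ValueError("lamb must be nonnegative")
        if not (0 < self.block_fraction <= 1):
            raise ValueError("block_fraction must lie in (0, 1]")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    def resolve_k(self, n_cells: int) -> int:
        """K actually used for a dataset of ``n_cells`` cells."""
        return self.n_clusters if self.n_clusters is not None else default_n_clusters(n_cells)
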