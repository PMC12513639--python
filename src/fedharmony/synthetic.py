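"""Multi-site synthetic single-cell-like data with known ground truth.

Cell types are Gaussian clusters: type means are drawn once in a
low-dimensional latent space and embedded into feature space through a
random linear map, giving the low-rank structure PCA recovers. Each site
adds a single additive offset vector in feature space (a linear,
per-cluster-removable batch effect) plus i.i.d. Gaussian noise. Ground
truth cell-type and site labels are returned for every cell, so
integration quality is measurable without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ScenarioConfig:
    """Design of one multi-site simulation.

    Defaults describe the standard evaluation scenario: three sites of
    1000 cells sharing four well-separated cell types in 50 features,
    with a moderate additive batch offset (norm 5) and unit Gaussian
    noise.

    ``celltype_proportions`` is a B x C row-simplex; zeros are allowed
    and model cell types missing from a site. ``None`` means uniform.
    """

    n_sites: int = 3
    cells_per_site: tuple[int, ...] = (1000, 1000, 1000)
    n_celltypes: int = 4
    n_features: int = 50
    celltype_proportions: tuple[tuple[float, ...], ...] | None = None
    batch_shift_scale: float = 5.0
    noise_sd: float = 1.0
    seed: int = 7
    latent_dim: int = 10
    celltype_spread: float = 5.0  # sd of latent type means
    poisson_counts: bool = False  # emit count matrices for log-normalization

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("config error: n_sites must be >= 1")
        if len(self.cells_per_site) != self.n_sites:
            raise ValueError("config error: need one cell count per site")
        if any(n < 1 for n in self.cells_per_site):
            raise ValueError("config error: every site needs N_b >= 1")
        if self.n_celltypes < 1:
            raise ValueError("config error: n_celltypes must be >= 1")
        if self.n_features < 2:
            raise ValueError("config error: n_features must be >= 2")
        if self.batch_shift_scale < 0 or self.noise_sd < 0:
            raise ValueError("config error: scales must be nonnegative")
        if self.celltype_proportions is not None:
            P = np.asarray(self.celltype_proportions, dtype=float)
            if P.shape != (self.n_sites, self.n_celltypes):
                raise ValueError("config error: proportions must be B x C")
            if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("config error: each proportion row must be a simplex")

    def proportions(self) -> np.ndarray:
        if self.celltype_proportions is None:
            return np.full((self.n_sites, self.n_celltypes), 1.0 / self.n_celltypes)
        return np.asarray(self.celltype_proportions, dtype=float)


@dataclass
class SyntheticDataset:
    """Per-site matrices (features x cells) with aligned label arrays."""

    matrices: list[np.ndarray]
    celltype_labels: list[np.ndarray]
    site_labels: list[np.ndarray]
    config: ScenarioConfig
    type_means: np.ndarray = field(repr=False, default=None)  # G x C, shared across sites
    site_offsets: np.ndarray = field(repr=False, default=None)  # G x B

    @property
    def n_sites(self) -> int:
        return len(self.matrices)

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pooled matrix (G x N) with pooled cell-type and site labels."""
        X = np.concatenate(self.matrices, axis=1)
        ct = np.concatenate(self.celltype_labels)
        st = np.concatenate(self.site_labels)
        return X, ct, st

    def write_csv(self, directory) -> None:
        """Dense per-site CSV matrices plus a (cell_id, label) TSV per site."""
        from . import io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        features = [f"feature{g}" for g in range(self.config.n_features)]
        for b, X in enumerate(self.matrices):
            cells = [f"site{b}_cell{i}" for i in range(X.shape[1])]
            io.write_dense_csv(directory / f"site{b}_matrix.csv", X, features, cells)
            io.write_labels_tsv(directory / f"site{b}_labels.tsv", cells,
                                self.celltype_labels[b])

    def write_mtx(self, directory) -> None:
        """Per-site MTX triplets (matrix.mtx, features.tsv, barcodes.tsv)."""
        from . import io

        directory = Path(directory)
        features = [f"feature{g}" for g in range(self.config.n_features)]
        for b, X in enumerate(self.matrices):
            cells = [f"site{b}_cell{i}" for i in range(X.shape[1])]
            io.write_mtx(directory / f"site{b}", X, features, cells)
            io.write_labels_tsv(directory / f"site{b}" / "labels.tsv", cells,
                                self.celltype_labels[b])


def generate_scenario(cfg: ScenarioConfig) -> SyntheticDataset:
    """Draw one dataset; fully reproducible from ``cfg.seed``.

    Type means are shared across sites; site b's cells are
    ``A mu_t + delta_b + noise`` with ``||delta_b|| = batch_shift_scale``.
    """
    rng = np.random.default_rng(cfg.seed)
    C, G, L = cfg.n_celltypes, cfg.n_features, cfg.latent_dim
    mu_latent = rng.normal(size=(C, L)) * cfg.celltype_spread
    A = rng.normal(size=(G, L)) / np.sqrt(L)
    type_means = A @ mu_latent.T  # G x C

    directions = rng.normal(size=(G, cfg.n_sites))
    directions /= np.linalg.norm(directions, axis=0)
    offsets = directions * cfg.batch_shift_scale  # G x B

    P = cfg.proportions()
    matrices, ct_labels, site_labels = [], [], []
    for b, n_b in enumerate(cfg.cells_per_site):
        types = rng.choice(C, size=n_b, p=P[b])
        X = type_means[:, types] + offsets[:, [b]]
        if cfg.noise_sd > 0:
            X = X + rng.normal(size=(G, n_b)) * cfg.noise_sd
        if cfg.poisson_counts:
            X = rng.poisson(np.clip(X - X.min(), 0, None)).astype(float)
        matrices.append(X)
        ct_labels.append(types)
        site_labels.append(np.full(n_b, b))
    return SyntheticDataset(matrices, ct_labels, site_labels, cfg, type_means, offsets)
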