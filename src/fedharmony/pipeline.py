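"""End-to-end orchestration: federated runs, the pooled reference, comparison.

A federated run mirrors the centralized loop round for round —
initialization, alternating clustering and correction phases until the
outer objective stabilizes — but every cross-site exchange is a typed,
audited message. With a single site and matched initial centroids and
block draws, the two paths coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as kern
from . import centralized, clustering, correction, initialization, metrics
from .config import Hyperparameters
from .federation import (
    SERVER,
    Message,
    MessageBus,
    ServerHandle,
    SiteHandle,
    SizeBook,
)


@dataclass
class FederatedResult:
    """Outputs of one federated integration run."""

    Z_corr_sites: list[np.ndarray]          # per-site corrected embeddings (input scale)
    objective_trace: list[list[float]]      # per-round inner objective traces
    n_rounds: int
    converged: bool
    bus: MessageBus
    sites: list[SiteHandle] = field(repr=False, default_factory=list)
    server: ServerHandle | None = field(repr=False, default=None)

    @property
    def Z_corr(self) -> np.ndarray:
        """Corrected embeddings concatenated in site order (evaluation only)."""
        return np.concatenate(self.Z_corr_sites, axis=1)


def initialize_federation(
    Z_sites: list[np.ndarray],
    hp: Hyperparameters,
    bus: MessageBus | None = None,
    init_Y: np.ndarray | None = None,
) -> tuple[list[SiteHandle], ServerHandle, MessageBus]:
    """Set up sites and server: centroids, local R, and the O/E bookkeeping."""
    if not Z_sites:
        raise ValueError("at least one site required")
    d = Z_sites[0].shape[0]
    if any(Z.shape[0] != d for Z in Z_sites):
        raise ValueError("all sites must share the embedding dimension d")
    counts = tuple(Z.shape[1] for Z in Z_sites)
    B, N = len(counts), sum(counts)
    K = hp.resolve_k(N)
    sizes = SizeBook(n_clusters=K, n_dims=d, n_sites=B, site_cell_counts=counts)
    if bus is None:
        bus = MessageBus(sizes)
    sites = [
        SiteHandle(b, Z.astype(float).copy(), kern.l2_normalize_columns(Z.astype(float)))
        for b, Z in enumerate(Z_sites)
    ]
    server = ServerHandle(sizes, cell_counts=np.asarray(counts, dtype=float))
    if init_Y is None:
        server.Y = initialization.federated_kmeans(sites, K, hp.seed, bus)
    else:
        server.Y = kern.l2_normalize_columns(np.asarray(init_Y, dtype=float))
    bus.next_round()
    rowsums = []
    for site in sites:
        site.R = initialization.init_R_site(site.Z_cos, server.Y, hp.sigma)
        rs = site.R.sum(axis=1)
        bus.send(Message(f"site{site.b}", "r_rowsum", {"rowsum": rs}))
        bus.send(Message(f"site{site.b}", "control",
                         {"n_cells": np.float64(site.n_cells)}))
        rowsums.append(rs)
    server.O, server.E, server.Pr_b = initialization.init_O_E(rowsums, counts)
    return sites, server, bus


def run_federated(
    Z_sites: list[np.ndarray],
    hp: Hyperparameters,
    bus: MessageBus | None = None,
    init_Y: np.ndarray | None = None,
) -> FederatedResult:
    """Federated Harmony over per-site d x N_b embeddings."""
    sites, server, bus = initialize_federation(Z_sites, hp, bus, init_Y)
    counts = tuple(Z.shape[1] for Z in Z_sites)
    d = Z_sites[0].shape[0]
    B, N = len(counts), sum(counts)
    K = hp.resolve_k(N)

    # --- outer loop: clustering phase then correction phase
    traces: list[list[float]] = []
    prev_obj: float | None = None
    converged = False
    n_rounds = 0
    for rnd in range(hp.max_rounds):
        n_rounds = rnd + 1
        traces.append(clustering.clustering_phase(sites, server, hp, bus, rnd))

        bus.next_round()  # moments gather
        T_sum = np.zeros((K, B + 1, d))
        S_sum = np.zeros((K, B + 1, B + 1))
        for site in sites:
            m = correction.compute_site_moments(site, B, bus)
            T_sum += m.T
            S_sum += m.S
        W = correction.solve_W(S_sum, T_sum, hp.lamb, hp.ridge_intercept)
        bus.next_round()  # factor broadcast
        bus.send(Message(SERVER, "correction_W", {"W": W}))
        for site in sites:
            site.Z_corr = correction.correct_site(site, W)
            site.Z_cos = kern.l2_normalize_columns(site.Z_corr)

        cur = traces[-1][-1]
        if prev_obj is not None and abs(prev_obj - cur) < hp.tol * abs(prev_obj):
            converged = True
            break
        prev_obj = cur
    return FederatedResult(
        Z_corr_sites=[site.Z_corr for site in sites],
        objective_trace=traces,
        n_rounds=n_rounds,
        converged=converged,
        bus=bus,
        sites=sites,
        server=server,
    )


def run_centralized(
    Z_sites: list[np.ndarray],
    hp: Hyperparameters,
    init_Y: np.ndarray | None = None,
) -> centralized.HarmonyResult:
    """Pooled-data reference run on the concatenation of the site embeddings."""
    counts = [Z.shape[1] for Z in Z_sites]
    phi = initialization.build_phi_bookkeeping(counts).dense()
    Z = np.concatenate(Z_sites, axis=1)
    return centralized.run_harmony(Z, phi, hp, init_Y=init_Y)


def compare(
    Z_sites: list[np.ndarray],
    hp: Hyperparameters,
    k_range=range(2, 11),
    perplexity: float = 30.0,
    compute_ilisi: bool = True,
    matched_init: bool = True,
) -> dict:
    """Run both paths with matched hyperparameters and compare the embeddings.

    With ``matched_init`` (default) both runs start from the same initial
    centroids — the federated k-means result, which is computable without
    pooling — so the comparison isolates the effect of federation
    (sequential within-site blocks, aggregated solves) from the seed
    luck of two independent k-means initializations.

    Returns a report with the per-k k-means ARI between the two corrected
    embeddings, its minimum over k, iLISI medians (input / federated /
    centralized), objective traces, round counts and the message-byte
    ledger of the federated run.
    """
    fed = run_federated(Z_sites, hp)
    init_Y = None
    if matched_init:
        # deterministic replica of the federated run's own initial centroids
        K = hp.resolve_k(sum(Z.shape[1] for Z in Z_sites))
        probe_sites = [
            SiteHandle(b, Z.astype(float), kern.l2_normalize_columns(Z.astype(float)))
            for b, Z in enumerate(Z_sites)
        ]
        init_Y = initialization.federated_kmeans(probe_sites, K, hp.seed)
    cen = run_centralized(Z_sites, hp, init_Y=init_Y)
    sweep = metrics.kmeans_ari_sweep(fed.Z_corr, cen.Z_corr, k_range, seed=hp.seed)
    site_labels = np.concatenate(
        [np.full(Z.shape[1], b) for b, Z in enumerate(Z_sites)]
    )
    report = {
        "ari_by_k": {int(r.k): float(r.ari) for r in sweep.itertuples()},
        "min_ari": float(sweep["ari"].min()),
        "fed_rounds": fed.n_rounds,
        "cen_rounds": cen.n_rounds,
        "fed_objective_trace": fed.objective_trace,
        "cen_objective_trace": cen.objective_trace,
        "message_bytes_per_round": fed.bus.bytes_per_round(),
        "message_bytes_total": fed.bus.total_bytes(),
    }
    if compute_ilisi:
        Z_before = np.concatenate(Z_sites, axis=1)
        report["ilisi_median"] = {
            "before": metrics.ilisi(Z_before, site_labels, perplexity).median,
            "federated": metrics.ilisi(fed.Z_corr, site_labels, perplexity).median,
            "centralized": metrics.ilisi(cen.Z_corr, site_labels, perplexity).median,
        }
    return report
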