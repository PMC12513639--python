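"""Site/server execution contract: typed messages, privacy audit, byte accounting.

Every payload that crosses the simulated wire has a shape that is a
function of (K, d, B, G) only — never of any site's cell count N_b. The
audit enforces this, the byte ledger makes the communication cost
measurable, and the federated modules route all their exchanges through a
:class:`MessageBus` so a full run leaves an auditable log.

Payload byte accounting uses float32 (4 bytes per value); computation
everywhere else is float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SERVER = "server"

#: Known message tags and what they carry.
TAGS = (
    "site_moments_pca",    # feature sums, second-moment matrix, cell count
    "local_centroid_sum",  # per-cluster coordinate sums (d x K) + counts (K)
    "r_rowsum",            # per-cluster soft-assignment row sums (K)
    "oe_state",            # co-occurrence matrices O and/or E (K x B)
    "global_centroids",    # broadcast centroids (d x K)
    "moments_TS",          # correction moments T (K x (B+1) x d), S (K x (B+1) x (B+1))
    "correction_W",        # broadcast correction factors (K x (B+1) x d)
    "control",             # scalars: objective partials, cell counts, flags
)


class PrivacyAuditError(RuntimeError):
    """A message failed the per-cell-data audit."""


@dataclass(frozen=True)
class SizeBook:
    """Dimensions the audit checks shapes against."""

    n_clusters: int                      # K
    n_dims: int                          # d
    n_sites: int                         # B
    n_features: int | None = None        # G (preprocessing only)
    site_cell_counts: tuple[int, ...] = ()  # all N_b


@dataclass
class Message:
    """One site<->server exchange.

    ``round`` is the communication round the message belongs to; ``None``
    lets the bus stamp its current round counter.
    """

    sender: str
    tag: str
    payload: dict[str, np.ndarray]
    round: int | None = None


@dataclass(frozen=True)
class AuditVerdict:
    passed: bool
    reason: str = ""
    warnings: tuple[str, ...] = ()


def _allowed_shapes(tag: str, sizes: SizeBook) -> set[tuple[int, ...]] | None:
    K, d, B, G = sizes.n_clusters, sizes.n_dims, sizes.n_sites, sizes.n_features
    if tag == "site_moments_pca":
        if G is None:
            return set()
        return {(G,), (G, G), ()}
    if tag == "local_centroid_sum":
        return {(d, K), (K,)}
    if tag == "r_rowsum":
        return {(K,)}
    if tag == "oe_state":
        # full matrices (site-to-site hand-off option) or the minimal
        # column exchange: O[:, b], rowsum(O), and the Pr_b scalar
        return {(K, B), (K,), ()}
    if tag == "global_centroids":
        return {(d, K)}
    if tag == "moments_TS":
        # dense per-cluster moments, or the compact wire encoding
        # (d x K weighted sums + K soft masses)
        return {(K, B + 1, d), (K, B + 1, B + 1), (d, K), (K,)}
    if tag == "correction_W":
        return {(K, B + 1, d)}
    if tag == "control":
        return {(), (1,), (3,), (B,)}
    return None


def audit_message(msg: Message, sizes: SizeBook) -> AuditVerdict:
    """Check that no payload axis is a per-cell axis.

    Fails iff the tag is unknown, or some payload axis length equals a
    site's cell count while the array's shape is not an allowed
    (K, d, B, G)-derived shape for the tag. A shape that is allowed but
    numerically collides with some N_b (e.g. N_b == K) passes with a
    warning — a documented limitation of a size-based audit.
    """
    allowed = _allowed_shapes(msg.tag, sizes)
    if allowed is None:
        return AuditVerdict(False, f"unknown message tag {msg.tag!r}")
    counts = set(sizes.site_cell_counts)
    warnings: list[str] = []
    for name, arr in msg.payload.items():
        shape = tuple(np.shape(arr))
        collides = [ax for ax in shape if ax in counts]
        if shape not in allowed:
            if collides:
                return AuditVerdict(
                    False,
                    f"payload {name!r} of tag {msg.tag!r} is a per-cell array: "
                    f"axis {collides[0]} equals a site cell count",
                )
            warnings.append(f"payload {name!r} has unexpected shape {shape} for tag {msg.tag!r}")
        elif collides:
            warnings.append(
                f"payload {name!r}: allowed axis {collides[0]} collides with a site "
                f"cell count (degenerate N_b == K/d/B); audit cannot distinguish"
            )
    return AuditVerdict(True, warnings=tuple(warnings))


def payload_float_count(tag: str, K: int, d: int, B: int, G: int | None = None) -> int:
    """Exact float count of one payload of the given tag.

    ``co_occurrence`` is an accounting alias for a single K x B matrix;
    ``oe_state`` is the full two-matrix exchange, ``oe_columns`` the
    minimal column hand-off actually used on the wire; ``moments_TS`` is
    the dense per-cluster moment payload, ``moments_compact`` its wire
    encoding.
    """
    if min(K, d, B) < 1:
        raise ValueError("sizes must be positive")
    table = {
        "global_centroids": K * d,
        "local_centroid_sum": K * d + K,
        "r_rowsum": K,
        "co_occurrence": K * B,
        "oe_state": 2 * K * B,
        "oe_columns": 2 * K + 1,
        "moments_TS": K * ((B + 1) * d + (B + 1) ** 2),
        "moments_compact": K * d + K,
        "correction_W": K * (B + 1) * d,
        "control": 1,
    }
    if tag == "site_moments_pca":
        if G is None:
            raise ValueError("site_moments_pca accounting requires G")
        return G + G * G + 1
    if tag not in table:
        raise ValueError(f"unknown tag {tag!r}")
    return table[tag]


@dataclass
class MessageRecord:
    round: int
    sender: str
    tag: str
    shapes: dict[str, tuple[int, ...]]
    n_floats: int
    n_bytes: int
    warnings: tuple[str, ...] = ()


@dataclass
class MessageBus:
    """In-process transport that audits and meters every send.

    ``strict`` raises :class:`PrivacyAuditError` on a failed audit;
    non-strict mode records the failure and lets the message through
    (useful only for negative tests).

    ``round`` counts communication rounds — one gather/broadcast exchange
    (a Lloyd step, an inner clustering iteration, a moments gather, a
    factor broadcast). Orchestrators call :meth:`next_round` at each
    boundary; messages without an explicit round are stamped with the
    current counter.
    """

    sizes: SizeBook
    strict: bool = True
    records: list[MessageRecord] = field(default_factory=list)
    round: int = 0

    def next_round(self) -> int:
        self.round += 1
        return self.round

    def send(self, msg: Message) -> Message:
        verdict = audit_message(msg, self.sizes)
        if not verdict.passed and self.strict:
            raise PrivacyAuditError(verdict.reason)
        n_floats = int(sum(np.asarray(a).size for a in msg.payload.values()))
        self.records.append(
            MessageRecord(
                round=msg.round if msg.round is not None else self.round,
                sender=msg.sender,
                tag=msg.tag,
                shapes={k: tuple(np.shape(v)) for k, v in msg.payload.items()},
                n_floats=n_floats,
                n_bytes=4 * n_floats,  # float32 wire format
                warnings=verdict.warnings,
            )
        )
        return msg

    def audit_all(self) -> list[AuditVerdict]:
        """Re-audit the recorded log by shape (payloads are elided in records)."""
        out = []
        for rec in self.records:
            msg = Message(rec.sender, rec.tag, {k: np.empty(s) for k, s in rec.shapes.items()}, rec.round)
            out.append(audit_message(msg, self.sizes))
        return out

    def bytes_per_round(self) -> dict[int, int]:
        per: dict[int, int] = {}
        for rec in self.records:
            per[rec.round] = per.get(rec.round, 0) + rec.n_bytes
        return per

    def total_bytes(self) -> int:
        return sum(rec.n_bytes for rec in self.records)

    def dump_jsonl(self, path) -> None:
        """Shapes and byte counts only; payload values are never written."""
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(
                    json.dumps(
                        {
                            "round": rec.round,
                            "sender": rec.sender,
                            "tag": rec.tag,
                            "shapes": {k: list(v) for k, v in rec.shapes.items()},
                            "n_floats": rec.n_floats,
                            "n_bytes": rec.n_bytes,
                        }
                    )
                    + "\n"
                )


@dataclass
class SiteHandle:
    """One institute's local state. Z and R never enter a Message payload."""

    b: int                    # site index
    Z_orig: np.ndarray        # d x N_b input embedding (local only)
    Z_cos: np.ndarray         # d x N_b normalized working embedding (local only)
    R: np.ndarray | None = None  # K x N_b soft assignments (local only)
    Z_corr: np.ndarray | None = None  # d x N_b corrected embedding (local only)

    @property
    def n_cells(self) -> int:
        return self.Z_orig.shape[1]


@dataclass
class ServerHandle:
    """Server-held global state: only cluster-level aggregates."""

    sizes: SizeBook
    Y: np.ndarray | None = None    # d x K
    O: np.ndarray | None = None    # K x B
    E: np.ndarray | None = None    # K x B
    Pr_b: np.ndarray | None = None  # length B
    cell_counts: np.ndarray | None = None  # length B (per-site totals)
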