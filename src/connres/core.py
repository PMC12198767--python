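"""Shared containers for connectome analysis.

Two objects travel through every stage of the pipeline: a weighted
functional connectome (region-by-region correlation matrix with a ledger of
removed nodes) and a fixed module partition (the a-priori assignment of
atlas regions to large-scale networks, 17 modules by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModulePartition",
    "WeightedConnectome",
    "RemovalReason",
    "region_name",
]

#: reasons a region may be absent from a connectome
RemovalReason = str
VALID_REMOVAL_REASONS = ("dropout", "primary_lesion", "attack")


def region_name(label: int) -> str:
    """Canonical node id for an integer atlas label (label 7 -> ``R007``)."""
    return f"R{int(label):03d}"


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every node to exactly one module.

    Parameters
    ----------
    node_ids
        Ordered region labels.
    module_ids
        Integer module index per node, aligned with ``node_ids``.
    """

    node_ids: tuple[str, ...]
    module_ids: np.ndarray

    def __post_init__(self) -> None:
        mods = np.asarray(self.module_ids, dtype=int)
        object.__setattr__(self, "module_ids", mods)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if mods.ndim != 1 or len(mods) != len(self.node_ids):
            raise ValueError("module_ids must align with node_ids")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in partition")
        object.__setattr__(
            self,
            "_index",
            {nid: i for i, nid in enumerate(self.node_ids)},
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.module_ids))

    def module_of(self, node_id: str) -> int:
        return int(self.module_ids[self._index[node_id]])

    def align(self, node_ids: Sequence[str]) -> np.ndarray:
        """Module index array for an arbitrary subset/ordering of nodes.

        Raises ``KeyError`` naming the first node absent from the partition.
        """
        try:
            idx = [self._index[nid] for nid in node_ids]
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} missing from partition") from None
        return self.module_ids[idx]

    def members(self, module_id: int) -> tuple[str, ...]:
        mask = self.module_ids == module_id
        return tuple(np.asarray(self.node_ids, dtype=object)[mask])


@dataclass
class WeightedConnectome:
    """Symmetric region-by-region weight matrix with a removed-node ledger.

    Correlation-derived weights lie in ``[-1, 1]`` with a unit diagonal.
    ``removed_nodes`` records ``(region_id, reason)`` pairs for regions that
    were deleted upstream (signal dropout, the subject's primary lesion, or
    a simulated attack); they are guaranteed disjoint from ``node_ids``.
    """

    node_ids: tuple[str, ...]
    weights: np.ndarray
    removed_nodes: tuple[tuple[str, RemovalReason], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.node_ids = tuple(self.node_ids)
        self.removed_nodes = tuple(self.removed_nodes)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0  # exact symmetry
        np.fill_diagonal(w, 1.0)
        self.weights = w
        removed_ids = {rid for rid, _ in self.removed_nodes}
        if removed_ids & set(self.node_ids):
            raise ValueError("removed_nodes overlap node_ids")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def removed_ids(self) -> frozenset[str]:
        return frozenset(rid for rid, _ in self.removed_nodes)

    def index_of(self, node_ids: Iterable[str]) -> np.ndarray:
        lookup = {nid: i for i, nid in enumerate(self.node_ids)}
        return np.asarray([lookup[nid] for nid in node_ids], dtype=int)

    def drop_nodes(
        self, node_ids: Iterable[str], reason: RemovalReason
    ) -> "WeightedConnectome":
        """Delete rows/columns and update the ledger; idempotent.

        Ids already absent (previously removed) are silently skipped so the
        operation can be replayed. Raises if fewer than 2 nodes would remain
        or if an id is entirely unknown.
        """
        if reason not in VALID_REMOVAL_REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        requested = set(node_ids)
        known = set(self.node_ids) | self.removed_ids
        unknown = requested - known
        if unknown:
            raise KeyError(f"unknown node ids: {sorted(unknown)}")
        to_drop = requested & set(self.node_ids)
        if not to_drop:
            return self
        keep = [i for i, nid in enumerate(self.node_ids) if nid not in to_drop]
        if len(keep) < 2:
            raise ValueError(
                f"removing {len(to_drop)} nodes would leave {len(keep)} < 2 nodes"
            )
        keep_idx = np.asarray(keep, dtype=int)
        new_ledger = self.removed_nodes + tuple(
            (nid, reason) for nid in self.node_ids if nid in to_drop
        )
        return WeightedConnectome(
            node_ids=tuple(self.node_ids[i] for i in keep),
            weights=self.weights[np.ix_(keep_idx, keep_idx)],
            removed_nodes=new_ledger,
        )
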