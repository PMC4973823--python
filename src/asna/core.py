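"""Core containers for animal social network data.

The raw substrate of gambit-of-the-group sampling is a sequence of observed
groups (one record per group seen in a sampling period), encoded as a binary
group-by-individual (GBI) matrix.  Every derived object — attribute tables,
dyad tallies, networks — is aligned to a single immutable ordering of
individual identities, so that row/column *i* always refers to the same
animal.  Mixing orderings between an adjacency matrix and an attribute table
is one of the classic silent errors in this kind of analysis, and the
:class:`IndividualRegistry` exists to make it structurally impossible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("asna")

__all__ = [
    "IndividualRegistry",
    "AttributeTable",
    "GroupObservation",
    "GroupByIndividual",
    "InteractionLog",
    "Network",
    "build_gbi",
]


class IndividualRegistry:
    """Immutable ordered set of unique individual labels.

    Position *i* in every matrix produced by this package corresponds to
    ``ids[i]``.
    """

    __slots__ = ("_ids", "_index")

    def __init__(self, ids: Iterable[str]):
        ids = tuple(str(i) for i in ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual labels: {dupes}")
        if not ids:
            raise ValueError("registry must contain at least one individual")
        self._ids = ids
        self._index = {label: i for i, label in enumerate(ids)}

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def index(self) -> Mapping[str, int]:
        return dict(self._index)

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __iter__(self):
        return iter(self._ids)

    def __eq__(self, other) -> bool:
        return isinstance(other, IndividualRegistry) and other._ids == self._ids

    def __hash__(self) -> int:
        return hash(self._ids)

    def __repr__(self) -> str:
        return f"IndividualRegistry({len(self)} individuals)"

    def positions(self, labels: Iterable[str]) -> np.ndarray:
        """Positions of ``labels``, raising with the offending labels listed."""
        labels = list(labels)
        unknown = [l for l in labels if l not in self._index]
        if unknown:
            raise KeyError(f"unknown individuals: {sorted(set(unknown))}")
        return np.array([self._index[l] for l in labels], dtype=np.intp)

    @classmethod
    def from_observations(cls, observations: Iterable["GroupObservation"]) -> "IndividualRegistry":
        """Registry in first-seen order over all group members."""
        seen: dict[str, None] = {}
        for obs in observations:
            for m in sorted(obs.members):
                seen.setdefault(m, None)
        return cls(seen.keys())


class AttributeTable:
    """Per-individual attributes, row order locked to a registry."""

    def __init__(self, registry: IndividualRegistry, data: pd.DataFrame | Mapping[str, Sequence]):
        df = pd.DataFrame(data)
        if len(df) != len(registry):
            raise ValueError(
                f"attribute table has {len(df)} rows for {len(registry)} individuals"
            )
        if "id" in df.columns:
            if sorted(df["id"].astype(str)) != sorted(registry.ids):
                raise ValueError("attribute ids do not match the registry")
            df = df.set_index(df["id"].astype(str)).drop(columns="id")
            df = df.loc[list(registry.ids)]
        else:
            df = df.copy()
            df.index = list(registry.ids)
        self.registry = registry
        self.table = df

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


@dataclass(frozen=True)
class GroupObservation:
    """One observed group: all members are taken to be associating."""

    period: str
    members: frozenset[str]
    time: float | None = None
    location: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("group observation with empty member set")
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))


class GroupByIndividual:
    """Binary K x N group-by-individual matrix with per-row sampling metadata.

    Rows are observed groups (sampling units), columns individuals in registry
    order.  ``row_meta`` carries ``period``, ``time`` and ``location`` per row.
    """

    def __init__(self, matrix: np.ndarray, row_meta: pd.DataFrame, registry: IndividualRegistry):
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("GBI matrix must be 2-D")
        if matrix.shape[0] == 0:
            raise ValueError("empty GBI (no group observations)")
        if matrix.shape[1] != len(registry):
            raise ValueError("GBI columns do not match registry size")
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("GBI entries must be 0/1")
        matrix = matrix.astype(np.uint8)
        if (matrix.sum(axis=1) < 1).any():
            bad = np.where(matrix.sum(axis=1) < 1)[0]
            raise ValueError(f"GBI rows with no members: {bad.tolist()}")
        row_meta = row_meta.reset_index(drop=True)
        for col in ("period", "time", "location"):
            if col not in row_meta.columns:
                row_meta[col] = None
        if len(row_meta) != matrix.shape[0]:
            raise ValueError("row_meta length does not match number of groups")
        self.matrix = matrix
        self.row_meta = row_meta[["period", "time", "location"]]
        self.registry = registry

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    def sighting_counts(self) -> np.ndarray:
        """Number of group records each individual appears in (column sums)."""
        return self.matrix.sum(axis=0).astype(int)

    def group_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)

    def periods(self) -> list:
        """Distinct sampling periods, in first-appearance order."""
        return list(pd.unique(self.row_meta["period"]))

    def copy(self) -> "GroupByIndividual":
        return GroupByIndividual(self.matrix.copy(), self.row_meta.copy(), self.registry)

    def subset_rows(self, rows: np.ndarray) -> "GroupByIndividual":
        return GroupByIndividual(
            self.matrix[rows], self.row_meta.iloc[rows].reset_index(drop=True), self.registry
        )


class InteractionLog:
    """Directed interaction records: actor -> receiver with a weight.

    Weights are counts or durations; the unit is whatever the observer used,
    declared in ``weight_unit``.
    """

    COLUMNS = ["actor", "receiver", "weight", "period", "location"]

    def __init__(self, records: pd.DataFrame, registry: IndividualRegistry, weight_unit: str = "count"):
        df = pd.DataFrame(records).copy()
        for col in ("period", "location"):
            if col not in df.columns:
                df[col] = None
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = [c for c in ("actor", "receiver") if c not in df.columns]
        if missing:
            raise ValueError(f"interaction log missing columns: {missing}")
        df["actor"] = df["actor"].astype(str)
        df["receiver"] = df["receiver"].astype(str)
        if (df["actor"] == df["receiver"]).any():
            raise ValueError("self-interactions (actor == receiver) are not allowed")
        if (df["weight"] < 0).any():
            raise ValueError("negative interaction weights")
        registry.positions(df["actor"])
        registry.positions(df["receiver"])
        self.records = df[self.COLUMNS].reset_index(drop=True)
        self.registry = registry
        self.weight_unit = weight_unit

    def __len__(self) -> int:
        return len(self.records)


EDGE_KINDS = ("association_index", "rate", "count", "residual", "binary")


class Network:
    """Weighted adjacency matrix plus identity bookkeeping.

    ``weights[i, j]`` is the edge from ``registry.ids[i]`` to
    ``registry.ids[j]``.  Self-edges are unused and forced to zero.  For
    undirected networks the matrix is symmetric; association-index edges live
    in [0, 1].  ``mask`` optionally marks dyads whose value is actually
    defined (sampled); unsampled dyads carry weight 0.
    """

    def __init__(
        self,
        weights: np.ndarray,
        registry: IndividualRegistry,
        directed: bool = False,
        edge_kind: str = "association_index",
        mask: np.ndarray | None = None,
    ):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if weights.shape[0] != len(registry):
            raise ValueError("adjacency size does not match registry")
        if edge_kind not in EDGE_KINDS:
            raise ValueError(f"edge_kind must be one of {EDGE_KINDS}")
        if edge_kind != "residual" and np.any(weights < 0):
            raise ValueError("negative edge weights")
        if np.any(np.diag(weights) != 0):
            warnings.warn("nonzero diagonal ignored (self-edges are unused)", stacklevel=2)
            weights = weights.copy()
            np.fill_diagonal(weights, 0.0)
        if not directed and not np.allclose(weights, weights.T, atol=1e-9):
            raise ValueError("undirected network requires a symmetric matrix")
        if edge_kind == "association_index" and np.any(weights > 1 + 1e-12):
            raise ValueError("association indices must lie in [0, 1]")
        self.weights = weights
        self.registry = registry
        self.directed = directed
        self.edge_kind = edge_kind
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != weights.shape:
                raise ValueError("mask shape mismatch")
        self.mask = mask

    @property
    def n(self) -> int:
        return len(self.registry)

    def dyad_values(self, include_unsampled: bool = True) -> np.ndarray:
        """Off-diagonal edge values (upper triangle if undirected)."""
        n = self.n
        if self.directed:
            sel = ~np.eye(n, dtype=bool)
        else:
            sel = np.triu(np.ones((n, n), dtype=bool), k=1)
        if not include_unsampled and self.mask is not None:
            sel = sel & self.mask
        return self.weights[sel]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.registry.ids)
        ids = self.registry.ids
        rows, cols = np.nonzero(self.weights)
        for r, c in zip(rows, cols):
            if not self.directed and r > c:
                continue
            g.add_edge(ids[r], ids[c], weight=float(self.weights[r, c]))
        return g

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph.Weighted_Adjacency(
            self.weights.tolist(),
            mode="directed" if self.directed else "upper",
            attr="weight",
            loops=False,
        )
        g.vs["name"] = list(self.registry.ids)
        return g


def build_gbi(
    observations: Sequence[GroupObservation],
    registry: IndividualRegistry | None = None,
) -> GroupByIndividual:
    """Encode group observations as a binary group-by-individual matrix.

    The registry defaults to first-seen order over members; pass an explicit
    roster to fix the ordering (and to retain never-observed individuals).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no group observations (empty GBI disallowed)")
    if registry is None:
        registry = IndividualRegistry.from_observations(observations)
    K, N = len(observations), len(registry)
    matrix = np.zeros((K, N), dtype=np.uint8)
    meta = {"period": [], "time": [], "location": []}
    for k, obs in enumerate(observations):
        matrix[k, registry.positions(sorted(obs.members))] = 1
        meta["period"].append(obs.period)
        meta["time"].append(obs.time)
        meta["location"].append(obs.location)
    return GroupByIndividual(matrix, pd.DataFrame(meta), registry)
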