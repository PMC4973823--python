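"""Readers and writers for the package's text formats.

Group stream CSV: one row per observed group with columns ``period``,
optional ``time`` and ``location``, and ``members`` (labels separated by
``;``).  Attribute CSV: one row per individual with an ``id`` column.
Networks round-trip through square CSV (header row and first column carry the
same ID ordering), edge-list CSV (``id1,id2,weight``), or GraphML.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AttributeTable,
    GroupByIndividual,
    GroupObservation,
    IndividualRegistry,
    Network,
    build_gbi,
)

logger = logging.getLogger("asna")

__all__ = [
    "read_group_observations",
    "read_gbi",
    "read_attributes",
    "write_network",
    "read_network",
]


def read_group_observations(
    path,
    member_sep: str = ";",
) -> list[GroupObservation]:
    """Parse a group stream CSV into :class:`GroupObservation` records.

    Malformed lines raise with the 1-based line number; a duplicate member
    within one group is a validation error.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"period", "members"}
    if not required.issubset(df.columns):
        raise ValueError(f"group stream file must have columns {sorted(required)}")
    observations = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        raw = row["members"]
        if pd.isna(raw) or not str(raw).strip():
            raise ValueError(f"line {lineno}: empty member list")
        members = [m.strip() for m in str(raw).split(member_sep) if m.strip()]
        if not members:
            raise ValueError(f"line {lineno}: empty member list")
        if len(set(members)) != len(members):
            raise ValueError(f"line {lineno}: duplicate member within a group")
        time = row.get("time")
        try:
            time = float(time) if time is not None and not pd.isna(time) else None
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {lineno}: unparseable time {time!r}") from exc
        location = row.get("location")
        location = None if location is None or pd.isna(location) else str(location)
        if pd.isna(row["period"]):
            raise ValueError(f"line {lineno}: missing period")
        observations.append(
            GroupObservation(
                period=str(row["period"]),
                members=frozenset(members),
                time=time,
                location=location,
            )
        )
    return observations


def read_gbi(path, roster=None, member_sep: str = ";") -> GroupByIndividual:
    """Group stream CSV straight to a GBI (roster overrides first-seen order)."""
    obs = read_group_observations(path, member_sep=member_sep)
    registry = IndividualRegistry(roster) if roster is not None else None
    return build_gbi(obs, registry)


def read_attributes(path, registry: IndividualRegistry | None = None) -> AttributeTable:
    """Attribute CSV (``id`` column + one column per trait) to a table.

    Without an explicit registry the file's row order defines the ordering —
    only safe if it was written against the same roster as the matrices.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("attribute file must have an 'id' column")
    df["id"] = df["id"].astype(str)
    if registry is None:
        registry = IndividualRegistry(df["id"])
    return AttributeTable(registry, df)


def write_network(net: Network, path, format: str = "square") -> None:
    """Write a network as square CSV, edge-list CSV, or GraphML."""
    path = Path(path)
    ids = list(net.registry.ids)
    if format == "square":
        pd.DataFrame(net.weights, index=ids, columns=ids).to_csv(path)
    elif format == "edgelist":
        rows = []
        r, c = np.nonzero(net.weights)
        for i, j in zip(r, c):
            if not net.directed and i > j:
                continue
            rows.append((ids[i], ids[j], net.weights[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "weight"]).to_csv(path, index=False)
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(
    path,
    format: str = "square",
    directed: bool = False,
    edge_kind: str = "association_index",
    registry: IndividualRegistry | None = None,
) -> Network:
    """Read a network written by :func:`write_network` (or a Data S1-style
    square half-weight matrix)."""
    path = Path(path)
    if format == "square":
        df = pd.read_csv(path, index_col=0)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        if row_ids != col_ids:
            raise ValueError("square CSV: row and column ID orderings differ")
        weights = df.to_numpy(dtype=float)
        if np.any(np.diag(weights) != 0):
            warnings.warn("nonzero diagonal in input ignored", stacklevel=2)
            np.fill_diagonal(weights, 0.0)
        reg = registry or IndividualRegistry(row_ids)
        return Network(weights, reg, directed=directed, edge_kind=edge_kind)
    if format == "edgelist":
        df = pd.read_csv(path, dtype={"id1": str, "id2": str})
        if registry is None:
            seen: dict[str, None] = {}
            for lab in pd.concat([df["id1"], df["id2"]]):
                seen.setdefault(str(lab), None)
            registry = IndividualRegistry(seen.keys())
        n = len(registry)
        weights = np.zeros((n, n))
        ii = registry.positions(df["id1"])
        jj = registry.positions(df["id2"])
        weights[ii, jj] = df["weight"].to_numpy(dtype=float)
        if not directed:
            weights[jj, ii] = df["weight"].to_numpy(dtype=float)
        return Network(weights, registry, directed=directed, edge_kind=edge_kind)
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = list(g.nodes())
        reg = registry or IndividualRegistry(nodes)
        n = len(reg)
        weights = np.zeros((n, n))
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            i, j = reg.positions([u])[0], reg.positions([v])[0]
            weights[i, j] = w
            if not g.is_directed():
                weights[j, i] = w
        return Network(weights, reg, directed=g.is_directed(), edge_kind=edge_kind)
    raise ValueError(f"unknown network format {format!r}")
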