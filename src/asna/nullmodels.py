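"""Constraint-respecting randomizations of social data.

Two families of null model are provided.  Node-label permutations shuffle an
attribute column over individuals while the network stays fixed — a weak null
that assumes the observed network is the true one.  Data-stream permutations
randomize the raw observations themselves by sequential checkerboard swaps:
two group records in the same stratum (e.g. same sampling period and
location) exchange one member each, which conserves every group size, every
individual's number of sightings, and all stratum totals.  Repeating swaps
yields an increasingly random data set from which any statistic can be
re-measured, giving a null distribution that inherits the sampling structure
of the real data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AttributeTable, GroupByIndividual, InteractionLog

logger = logging.getLogger("asna")

__all__ = [
    "PermutationConfig",
    "GroupSwapSampler",
    "permute_node_labels",
    "permute_datastream_groups",
    "permute_datastream_dyadic",
    "null_distribution",
]


@dataclass
class PermutationConfig:
    """Settings shared by all randomization streams.

    ``constraints`` names row-metadata keys (``period``, ``location``, or any
    custom column) whose cross-product defines the strata within which swaps
    are allowed.  ``burn_in`` swaps are performed before the first replicate
    is emitted and ``swaps_per_step`` between successive replicates;
    successive replicates of a sequential chain are serially correlated, so
    increase ``swaps_per_step`` to thin.
    """

    kind: str = "datastream_group"
    n_permutations: int = 1000
    swaps_per_step: int = 1
    constraints: tuple = ("period",)
    seed: int | None = None
    burn_in: int = 1000
    max_proposals: int = 1_000_000

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.seed is None:
            self.seed = 0
            logger.info("no seed supplied; defaulting to seed=0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _strata_keys(meta: pd.DataFrame, constraints) -> np.ndarray:
    """Integer stratum label per row from the cross-product of constraint keys."""
    if not constraints:
        warnings.warn("no constraints: all rows treated as one exchangeable stratum",
                      stacklevel=3)
        return np.zeros(len(meta), dtype=int)
    parts = []
    for key in constraints:
        if key not in meta.columns:
            raise ValueError(f"constraint key {key!r} not present in row metadata")
        col = meta[key]
        if col.isna().all():
            warnings.warn(
                f"constraint {key!r} is entirely missing; treating all rows as one "
                f"stratum for this key", stacklevel=3)
        parts.append(col.fillna("__missing__").astype(str))
    combined = parts[0]
    for p in parts[1:]:
        combined = combined + "\x1f" + p
    return pd.factorize(combined)[0]


class GroupSwapSampler:
    """Sequential checkerboard swaps on a group-by-individual matrix.

    A swap picks two group rows in the same stratum and two individuals with
    the sub-pattern [[1,0],[0,1]] and flips it to [[0,1],[1,0]].  Proposals
    without a valid checkerboard are rejected and resampled (not counted);
    exceeding ``max_proposals`` consecutive rejections raises, signalling
    constraint saturation.
    """

    def __init__(self, gbi: GroupByIndividual, constraints=("period",),
                 rng: np.random.Generator | None = None,
                 max_proposals: int = 1_000_000):
        self.matrix = gbi.matrix.astype(bool).copy()
        self.row_meta = gbi.row_meta
        self.registry = gbi.registry
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.max_proposals = max_proposals
        strata = _strata_keys(gbi.row_meta, constraints)
        self._stratum_rows = [np.where(strata == s)[0]
                              for s in np.unique(strata)
                              if (strata == s).sum() >= 2]
        if not self._stratum_rows:
            raise ValueError("no stratum contains two rows; no swap is possible")
        sizes = np.array([len(r) for r in self._stratum_rows], dtype=float)
        self._stratum_p = sizes * (sizes - 1)
        self._stratum_p /= self._stratum_p.sum()
        self.swap_count = 0

    def step(self) -> tuple[int, int, int, int]:
        """One accepted swap; returns (row1, row2, individual_out, individual_in)."""
        M = self.matrix
        rng = self.rng
        for _ in range(self.max_proposals):
            s = rng.choice(len(self._stratum_rows), p=self._stratum_p)
            rows = self._stratum_rows[s]
            r1, r2 = rows[rng.choice(len(rows), size=2, replace=False)]
            only1 = np.where(M[r1] & ~M[r2])[0]
            only2 = np.where(M[r2] & ~M[r1])[0]
            if len(only1) == 0 or len(only2) == 0:
                continue
            i = only1[rng.integers(len(only1))]
            j = only2[rng.integers(len(only2))]
            M[r1, i] = False
            M[r2, i] = True
            M[r2, j] = False
            M[r1, j] = True
            self.swap_count += 1
            return int(r1), int(r2), int(i), int(j)
        raise RuntimeError(
            f"no valid checkerboard swap found in {self.max_proposals} proposals: "
            f"constraints are saturated"
        )

    def run(self, n_swaps: int) -> None:
        for _ in range(n_swaps):
            self.step()

    def snapshot(self) -> GroupByIndividual:
        gbi = GroupByIndividual(self.matrix.astype(np.uint8), self.row_meta.copy(),
                                self.registry)
        gbi.swap_count = self.swap_count
        return gbi


def permute_node_labels(attributes: AttributeTable, column: str,
                        config: PermutationConfig):
    """Stream of independent uniform permutations of one attribute column.

    The network itself is untouched; each replicate preserves the exact
    multiset of attribute values.
    """
    if column not in attributes.columns:
        raise ValueError(f"attribute column {column!r} does not exist")
    values = attributes.column(column)
    if len(pd.unique(values)) == 1:
        warnings.warn(f"attribute {column!r} is constant; the test will be powerless",
                      stacklevel=2)
    rng = config.rng()
    for _ in range(config.n_permutations):
        yield values[rng.permutation(len(values))]


def permute_datastream_groups(gbi: GroupByIndividual, config: PermutationConfig):
    """Stream of sequentially randomized GBIs via constrained group swaps.

    Emits ``n_permutations`` snapshots, the first after ``burn_in`` swaps and
    subsequent ones every ``swaps_per_step`` swaps, each tagged with its
    cumulative swap count (``.swap_count``).
    """
    sampler = GroupSwapSampler(gbi, constraints=config.constraints, rng=config.rng(),
                               max_proposals=config.max_proposals)
    sampler.run(config.burn_in)
    for _ in range(config.n_permutations):
        sampler.run(config.swaps_per_step)
        yield sampler.snapshot()


def permute_datastream_dyadic(log: InteractionLog, config: PermutationConfig):
    """Stream of interaction logs with receivers swapped within strata.

    A swap exchanges the receivers of two records in the same stratum
    (A->C, B->D becomes A->D, B->C), conserving every individual's out- and
    in-interaction counts.
    """
    records = log.records.copy()
    strata = _strata_keys(records, config.constraints)
    groups = [np.where(strata == s)[0] for s in np.unique(strata)]
    valid = [g for g in groups if len(g) >= 2 and records["receiver"].iloc[g].nunique() > 1]
    if not valid:
        raise ValueError("no stratum has two records with distinct receivers")
    sizes = np.array([len(g) for g in valid], dtype=float)
    p = sizes * (sizes - 1)
    p /= p.sum()
    rng = config.rng()
    actors = records["actor"].to_numpy().copy()
    receivers = records["receiver"].to_numpy().copy()

    def swap_once():
        for _ in range(config.max_proposals):
            g = valid[rng.choice(len(valid), p=p)]
            a, b = g[rng.choice(len(g), size=2, replace=False)]
            # keep actor != receiver and receivers distinct after the exchange
            if receivers[a] == receivers[b]:
                continue
            if actors[a] == receivers[b] or actors[b] == receivers[a]:
                continue
            receivers[a], receivers[b] = receivers[b], receivers[a]
            return
        raise RuntimeError("no valid dyadic swap found: constraints are saturated")

    for _ in range(config.burn_in):
        swap_once()
    total = config.burn_in
    for _ in range(config.n_permutations):
        for _ in range(config.swaps_per_step):
            swap_once()
        total += config.swaps_per_step
        out = records.copy()
        out["actor"] = actors
        out["receiver"] = receivers
        new_log = InteractionLog(out, log.registry, weight_unit=log.weight_unit)
        new_log.swap_count = total
        yield new_log


def null_distribution(stream, statistic) -> np.ndarray:
    """Apply a scalar statistic to every replicate of a permutation stream."""
    values = []
    for k, replicate in enumerate(stream):
        try:
            values.append(float(statistic(replicate)))
        except Exception as exc:  # noqa: BLE001 - annotate with replicate index
            raise RuntimeError(f"statistic failed on replicate {k}: {exc}") from exc
    return np.asarray(values)
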