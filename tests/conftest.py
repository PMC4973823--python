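import numpy as np
import pandas as pd
import pytest

from asna.core import (
    AttributeTable,
    GroupByIndividual,
    GroupObservation,
    IndividualRegistry,
    Network,
    build_gbi,
)


@pytest.fixture
def toy_observations():
    """The worked three-group stream: (P1:{a,b}), (P1:{c}), (P2:{a,c})."""
    return [
        GroupObservation("P1", frozenset({"a", "b"})),
        GroupObservation("P1", frozenset({"c"})),
        GroupObservation("P2", frozenset({"a", "c"})),
    ]


@pytest.fixture
def toy_gbi(toy_observations):
    return build_gbi(toy_observations)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_gbi(rng, n_individuals=6, n_periods=8, n_groups_per_period=3,
               p_member=0.45, locations=None):
    """Random GBI helper used across suites (every row non-empty)."""
    ids = [chr(ord("a") + k) for k in range(n_individuals)]
    registry = IndividualRegistry(ids)
    rows, meta = [], {"period": [], "time": [], "location": []}
    for p in range(n_periods):
        for g in range(n_groups_per_period):
            row = rng.random(n_individuals) < p_member
            if not row.any():
                row[rng.integers(n_individuals)] = True
            rows.append(row.astype(np.uint8))
            meta["period"].append(f"P{p}")
            meta["time"].append(float(p))
            meta["location"].append(
                None if locations is None else locations[rng.integers(len(locations))]
            )
    return GroupByIndividual(np.array(rows), pd.DataFrame(meta), registry)


def network_from_edges(n, edges, weights=None, ids=None):
    """Small undirected network builder for metric tests."""
    ids = ids or [str(k) for k in range(n)]
    registry = IndividualRegistry(ids)
    W = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        W[i, j] = W[j, i] = w
    return Network(W, registry, directed=False, edge_kind="count")
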