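"""From observation streams to weighted networks.

The association index of a dyad estimates the proportion of sampling units in
which the two animals were together.  With ``x`` units together, ``y_AB``
units where both were identified but in different groups, and ``y_A``/``y_B``
units where only one was identified:

    simple ratio index   SRI = x / (x + y_AB + y_A + y_B)
    half-weight index    HWI = x / (x + y_AB + (y_A + y_B) / 2)

SRI is appropriate when joint observations are rarely missed; HWI halves the
solo-sighting terms to reduce the downward bias when individuals that were
together are often recorded apart.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GroupByIndividual, IndividualRegistry, InteractionLog, Network

logger = logging.getLogger("asna")

__all__ = [
    "DyadTally",
    "tally_dyads",
    "association_index",
    "interaction_rate_network",
    "AffiliationModelSpec",
    "generalized_affiliation_index",
    "threshold_network",
    "filter_individuals",
    "period_cooccurrence",
]


@dataclass
class DyadTally:
    """Sufficient statistics of the association indices.

    ``y_only[i, j]`` counts sampling units where *i* was identified and *j*
    was not; the conventional y_A / y_B for dyad (A, B) are ``y_only[A, B]``
    and ``y_only[B, A]``.  ``d = x + y_AB + y_A + y_B`` is the number of units
    where at least one of the pair was identified.
    """

    x: np.ndarray
    y_ab: np.ndarray
    y_only: np.ndarray
    d: np.ndarray
    n_units: int
    registry: IndividualRegistry
    unit: str = "period"

    def __post_init__(self):
        for name in ("x", "y_ab"):
            m = getattr(self, name)
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if (self.x < 0).any() or (self.y_ab < 0).any() or (self.y_only < 0).any():
            raise ValueError("tally counts must be non-negative")
        if (self.x > self.d).any():
            raise ValueError("x cannot exceed the dyad denominator")
        if (self.d > self.n_units).any():
            raise ValueError("dyad denominator cannot exceed the number of units")


def period_cooccurrence(gbi: GroupByIndividual, period_mode: str = "per-period-union"):
    """Per-sampling-unit togetherness and identification arrays.

    Returns ``(together, identified)`` where ``together`` is a
    (units x N x N) boolean array (shared at least one group row in the unit)
    and ``identified`` a (units x N) boolean array.  Sampling units are GBI
    rows (``per-row``) or unique period labels (``per-period-union``).
    """
    M = gbi.matrix.astype(bool)
    if period_mode == "per-row":
        together = M[:, :, None] & M[:, None, :]
        identified = M
    elif period_mode == "per-period-union":
        periods = gbi.periods()
        labels = gbi.row_meta["period"].to_numpy()
        together = np.zeros((len(periods), gbi.n_individuals, gbi.n_individuals), dtype=bool)
        identified = np.zeros((len(periods), gbi.n_individuals), dtype=bool)
        for k, p in enumerate(periods):
            rows = M[labels == p]
            together[k] = (rows.T.astype(np.int32) @ rows.astype(np.int32)) > 0
            identified[k] = rows.any(axis=0)
    else:
        raise ValueError("period_mode must be 'per-row' or 'per-period-union'")
    idx = np.arange(together.shape[1])
    together[:, idx, idx] = False
    return together, identified


def tally_dyads(gbi: GroupByIndividual, period_mode: str = "per-period-union") -> DyadTally:
    """Count x, y_AB, y_A, y_B for every dyad.

    ``per-period-union`` pools all group rows sharing a period label into one
    sampling unit (two animals are "together" if they shared any group that
    period); ``per-row`` treats every group record as its own unit.
    """
    together, identified = period_cooccurrence(gbi, period_mode)
    x = together.sum(axis=0).astype(np.int64)
    I = identified.astype(np.int64)
    both = I.T @ I  # units where both identified
    counts = I.sum(axis=0)
    y_ab = both - x
    np.fill_diagonal(y_ab, 0)
    y_only = counts[:, None] - both
    np.fill_diagonal(y_only, 0)
    d = counts[:, None] + counts[None, :] - both
    np.fill_diagonal(d, 0)
    return DyadTally(
        x=x, y_ab=y_ab, y_only=y_only, d=d,
        n_units=together.shape[0], registry=gbi.registry,
        unit="row" if period_mode == "per-row" else "period",
    )


def association_index(tally: DyadTally, method: str = "SRI") -> Network:
    """Association-index network from a dyad tally (SRI or HWI).

    Dyads never sampled (denominator 0) get weight 0 and are flagged in the
    network's ``mask`` so downstream statistics can exclude them.
    """
    method = method.upper()
    x = tally.x.astype(float)
    if method == "SRI":
        denom = tally.d.astype(float)
    elif method == "HWI":
        denom = tally.x + tally.y_ab + 0.5 * (tally.y_only + tally.y_only.T)
    else:
        raise ValueError(f"unknown association index {method!r} (use 'SRI' or 'HWI')")
    mask = tally.d > 0
    weights = np.zeros_like(x)
    np.divide(x, denom, out=weights, where=denom > 0)
    np.fill_diagonal(weights, 0.0)
    return Network(weights, tally.registry, directed=False,
                   edge_kind="association_index", mask=mask)


def interaction_rate_network(log: InteractionLog, exposure) -> Network:
    """Directed interaction-rate network: total weight divided by effort.

    ``exposure`` is a scalar, a per-individual mapping/array (actor effort),
    or an N x N per-dyad matrix.  A zero exposure with a nonzero count is an
    error; the asymmetry of who-does-what-to-whom is preserved.
    """
    registry = log.registry
    n = len(registry)
    totals = np.zeros((n, n))
    if len(log):
        i = registry.positions(log.records["actor"])
        j = registry.positions(log.records["receiver"])
        np.add.at(totals, (i, j), log.records["weight"].to_numpy(dtype=float))
    if np.isscalar(exposure):
        expo = np.full((n, n), float(exposure))
    else:
        arr = np.asarray(
            [exposure[i] for i in registry.ids] if isinstance(exposure, dict) else exposure,
            dtype=float,
        )
        expo = np.broadcast_to(arr[:, None], (n, n)).copy() if arr.ndim == 1 else arr
    if np.any((expo <= 0) & (totals > 0)):
        bad = np.where((expo <= 0) & (totals > 0))
        raise ValueError(
            f"zero exposure with nonzero interaction count for dyads {list(zip(*bad))[:5]}"
        )
    rates = np.zeros_like(totals)
    np.divide(totals, expo, out=rates, where=expo > 0)
    np.fill_diagonal(rates, 0.0)
    return Network(rates, registry, directed=True, edge_kind="rate")


@dataclass
class AffiliationModelSpec:
    """Structural predictors to regress out of association values.

    ``predictors`` maps names to N x N symmetric matrices (e.g. spatial
    overlap, joint gregariousness).  ``family='binomial'`` models x successes
    of d trials (requires a :class:`DyadTally`); ``'identity'`` is ordinary
    least squares on precomputed edge values.
    """

    predictors: dict = field(default_factory=dict)
    family: str = "binomial"


def generalized_affiliation_index(source, spec: AffiliationModelSpec) -> Network:
    """Residual "affiliation" network after regressing out structural predictors.

    Returns a network of regression residuals (deviance residuals under the
    binomial family), isolating association beyond what the predictors
    explain.  Residuals can be negative; edge_kind is ``residual``.
    """
    import statsmodels.api as sm

    if not spec.predictors:
        raise ValueError("at least one structural predictor is required")
    if isinstance(source, DyadTally):
        registry = source.registry
        mask = source.d > 0
    elif isinstance(source, Network):
        registry = source.registry
        mask = source.mask if source.mask is not None else np.ones_like(source.weights, bool)
        if spec.family == "binomial":
            raise ValueError("binomial family requires a DyadTally (x of d trials)")
    else:
        raise TypeError("source must be a DyadTally or Network")
    n = len(registry)
    sel = np.triu(np.ones((n, n), bool), k=1) & mask

    names, cols = [], []
    for name in spec.predictors:
        P = np.asarray(spec.predictors[name], dtype=float)
        if P.shape != (n, n):
            raise ValueError(f"predictor {name!r} has shape {P.shape}, expected {(n, n)}")
        if not np.allclose(P, P.T, atol=1e-9):
            raise ValueError(f"predictor {name!r} must be symmetric for undirected data")
        vals = P[sel]
        if np.ptp(vals) == 0:
            # constant over dyads: absorbed by the intercept
            logger.info("predictor %r is constant across dyads; absorbed by intercept",
                        name)
            continue
        names.append(name)
        cols.append(vals)
    X = np.column_stack([np.ones(sel.sum())] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_names(X[:, 1:], names)
        raise ValueError(f"singular predictor set; collinear predictors: {collinear}")

    if spec.family == "binomial":
        successes = source.x[sel].astype(float)
        trials = source.d[sel].astype(float)
        model = sm.GLM(np.column_stack([successes, trials - successes]), X,
                       family=sm.families.Binomial())
        resid = model.fit().resid_deviance
    elif spec.family == "identity":
        y = source.weights[sel]
        resid = sm.OLS(y, X).fit().resid
    else:
        raise ValueError("family must be 'binomial' or 'identity'")

    weights = np.zeros((n, n))
    weights[sel] = resid
    weights = weights + weights.T
    out_mask = sel | sel.T
    return Network(weights, registry, directed=False, edge_kind="residual", mask=out_mask)


def _collinear_names(cols: np.ndarray, names: list[str]) -> list[str]:
    """Predictors (nearly) reproducible from the others, by leave-one-out R^2."""
    flagged = []
    for k in range(cols.shape[1]):
        others = np.column_stack(
            [np.ones(cols.shape[0])] + [cols[:, m] for m in range(cols.shape[1]) if m != k]
        )
        beta, *_ = np.linalg.lstsq(others, cols[:, k], rcond=None)
        resid = cols[:, k] - others @ beta
        tot = np.var(cols[:, k]) * cols.shape[0]
        if tot == 0 or 1 - resid @ resid / tot > 1 - 1e-8:
            flagged.append(names[k])
    return flagged or names


def threshold_network(net: Network, t: float, mode: str = "binarize") -> Network:
    """Keep edges strictly greater than ``t`` (binarized or at original weight).

    Thresholding discards information and inflates both false-positive and
    false-negative rates; it is offered for display and exploratory use and
    logs a warning accordingly.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    logger.warning(
        "thresholding a weighted network inflates type I and type II error rates; "
        "prefer the weighted network for analysis"
    )
    keep = net.weights > t
    if mode == "binarize":
        weights = keep.astype(float)
        kind = "binary"
    elif mode == "prune":
        weights = np.where(keep, net.weights, 0.0)
        kind = net.edge_kind
    else:
        raise ValueError("mode must be 'binarize' or 'prune'")
    np.fill_diagonal(weights, 0.0)
    return Network(weights, net.registry, directed=net.directed, edge_kind=kind, mask=net.mask)


def filter_individuals(gbi: GroupByIndividual, min_observations: int):
    """Drop individuals seen fewer than ``min_observations`` times.

    Group rows emptied by the removal are dropped too.  Returns
    ``(filtered_gbi, removed_ids)``.
    """
    if min_observations < 0:
        raise ValueError("min_observations must be >= 0")
    counts = gbi.sighting_counts()
    keep = counts >= min_observations
    if not keep.any():
        raise ValueError("all individuals would be removed")
    removed = [gbi.registry.ids[i] for i in np.where(~keep)[0]]
    if not removed:
        return gbi.copy(), []
    registry = IndividualRegistry([gbi.registry.ids[i] for i in np.where(keep)[0]])
    matrix = gbi.matrix[:, keep]
    nonempty = matrix.sum(axis=1) > 0
    out = GroupByIndividual(
        matrix[nonempty],
        gbi.row_meta.iloc[nonempty].reset_index(drop=True),
        registry,
    )
    logger.info("filter_individuals removed %d individuals: %s", len(removed), removed)
    return out, removed
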