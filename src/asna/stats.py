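"""Hypothesis tests and precision/power estimation for social networks.

All tests share one inferential pattern: a statistic is measured on the
observed network, re-measured on many randomized versions of the underlying
data, and the p-value is the proportion of randomized values at least as
extreme as the observed one.  Permutation nulls sidestep the non-independence
of network measures (every edge is shared by two individuals) that breaks the
assumptions of ordinary parametric tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import association_index, period_cooccurrence, tally_dyads
from .core import AttributeTable, GroupByIndividual, Network
from .lmm import ModelFit, RandomInterceptModel
from .nullmodels import GroupSwapSampler, PermutationConfig, permute_datastream_groups

logger = logging.getLogger("asna")

__all__ = [
    "TestResult",
    "LARCurve",
    "PowerEstimate",
    "network_cv",
    "preferred_association_test",
    "parse_formula",
    "design_matrix",
    "coefficient_permutation_test",
    "mantel_test",
    "mrqap_dsp",
    "lagged_association_rate",
    "bootstrap_metric_ci",
    "split_half_repeatability",
    "sampling_correlation",
    "required_sampling_effort",
    "strength_pipeline",
]


@dataclass
class TestResult:
    """Observed statistic, its permutation null distribution and p-value."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    p_value: float
    effect_size: dict
    n_permutations: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if len(self.null_values) != self.n_permutations:
            raise ValueError("null distribution length does not match n_permutations")


def _permutation_pvalue(observed: float, null: np.ndarray, tail: str,
                        strict: bool = False, conservative: bool = False) -> float:
    """#extreme / n (optionally the add-one conservative variant)."""
    null = np.asarray(null, dtype=float)
    if tail == "upper":
        extreme = null > observed if strict else null >= observed
    elif tail == "lower":
        extreme = null < observed if strict else null <= observed
    elif tail == "two_sided":
        extreme = np.abs(null) > abs(observed) if strict else np.abs(null) >= abs(observed)
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two_sided'")
    k, n = int(extreme.sum()), len(null)
    return (k + 1) / (n + 1) if conservative else k / n


# ---------------------------------------------------------------------------
# CV test for preferred/avoided associations
# ---------------------------------------------------------------------------

def network_cv(net: Network, include_zero_dyads: bool = True) -> float:
    """Coefficient of variation (sd/mean) of the dyadic edge values.

    An elevated CV relative to a null model indicates preferred and avoided
    relationships.  With ``include_zero_dyads=False`` dyads flagged as
    unsampled in the network mask are excluded.
    """
    vals = net.dyad_values(include_unsampled=include_zero_dyads)
    if len(vals) < 2:
        raise ValueError("CV requires at least two dyads")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV undefined: mean edge value is zero")
    return float(vals.std(ddof=0) / mean)


class _SwapIndexStream:
    """Association-index matrices along a constrained group-swap chain.

    When swaps are stratified by sampling period (per-period-union tallies),
    both the SRI and the HWI denominators are invariant under swaps — they
    depend only on who was identified in which period — so each replicate
    only needs the together-count matrix x updated incrementally around the
    two swapped individuals.  Otherwise the tally is recomputed from scratch
    per replicate.
    """

    def __init__(self, gbi: GroupByIndividual, config: PermutationConfig,
                 index: str = "SRI", period_mode: str = "per-period-union"):
        self.gbi = gbi
        self.config = config
        self.index = index.upper()
        self.period_mode = period_mode
        self.fast = (
            period_mode == "per-period-union" and "period" in config.constraints
        )
        tally = tally_dyads(gbi, period_mode)
        self.mask = tally.d > 0
        if self.index == "SRI":
            denom = tally.d.astype(float)
        elif self.index == "HWI":
            denom = tally.x + tally.y_ab + 0.5 * (tally.y_only + tally.y_only.T)
        else:
            raise ValueError("index must be 'SRI' or 'HWI'")
        with np.errstate(divide="ignore"):
            self.inv_d = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)

    def observed_weights(self) -> np.ndarray:
        tally = tally_dyads(self.gbi, self.period_mode)
        return tally.x * self.inv_d

    def __iter__(self):
        if self.fast:
            yield from self._iter_fast()
        else:
            yield from self._iter_generic()

    def _iter_generic(self):
        for snap in permute_datastream_groups(self.gbi, self.config):
            tally = tally_dyads(snap, self.period_mode)
            if self.index == "SRI":
                yield association_index(tally, "SRI").weights
            else:
                yield association_index(tally, "HWI").weights

    def _iter_fast(self):
        from . import _fastswap

        if _fastswap.HAVE_NUMBA:
            yield from self._iter_fast_numba()
        else:
            yield from self._iter_fast_python()

    def _iter_fast_numba(self):
        from ._fastswap import run_chain
        from .nullmodels import _strata_keys

        cfg = self.config
        gbi = self.gbi
        strata = _strata_keys(gbi.row_meta, cfg.constraints)
        order = np.argsort(strata, kind="stable")
        counts = np.bincount(strata)
        usable = counts >= 2
        if not usable.any():
            raise ValueError("no stratum contains two rows; no swap is possible")
        strat_rows = order[np.isin(strata[order], np.where(usable)[0])].astype(np.int64)
        sizes = counts[usable].astype(float)
        strat_offsets = np.concatenate([[0], np.cumsum(counts[usable])]).astype(np.int64)
        weights = sizes * (sizes - 1)
        strat_cum = np.cumsum(weights / weights.sum())
        strat_cum[-1] = 1.0 + 1e-12

        periods = gbi.periods()
        period_codes = pd.Categorical(gbi.row_meta["period"], categories=periods) \
            .codes.astype(np.int64)
        per_order = np.argsort(period_codes, kind="stable")
        per_counts = np.bincount(period_codes, minlength=len(periods))
        per_offsets = np.concatenate([[0], np.cumsum(per_counts)]).astype(np.int64)
        per_rows = per_order.astype(np.int64)

        together, _ = period_cooccurrence(gbi, "per-period-union")
        x = together.sum(axis=0).astype(np.int32)
        M = gbi.matrix.astype(bool).copy()
        seed = int(cfg.rng().integers(2**31 - 1))
        out = np.empty((cfg.n_permutations, gbi.n_individuals, gbi.n_individuals),
                       dtype=np.float64)
        ok = run_chain(M, strat_offsets, strat_rows, strat_cum, period_codes,
                       per_offsets, per_rows, together, x,
                       self.inv_d.astype(np.float64), cfg.burn_in,
                       cfg.n_permutations, cfg.swaps_per_step, seed,
                       cfg.max_proposals, out)
        if not ok:
            raise RuntimeError(
                f"no valid checkerboard swap found in {cfg.max_proposals} proposals: "
                f"constraints are saturated"
            )
        yield from out

    def _iter_fast_python(self):
        cfg = self.config
        sampler = GroupSwapSampler(self.gbi, constraints=cfg.constraints,
                                   rng=cfg.rng(), max_proposals=cfg.max_proposals)
        together, _ = period_cooccurrence(self.gbi, "per-period-union")
        x = together.sum(axis=0).astype(np.int32)
        periods = self.gbi.periods()
        period_codes = pd.Categorical(self.gbi.row_meta["period"], categories=periods).codes
        rows_by_period = [np.where(period_codes == k)[0] for k in range(len(periods))]
        M = sampler.matrix

        def do_swaps(n_swaps):
            for _ in range(n_swaps):
                r1, r2, i, j = sampler.step()
                p = period_codes[r1]
                rows = rows_by_period[p]
                Mp = M[rows]
                for a in (i, j):
                    new_t = Mp[Mp[:, a]].any(axis=0)
                    new_t[a] = False
                    delta = new_t.astype(np.int32) - together[p, a].astype(np.int32)
                    if delta.any():
                        x[a, :] += delta
                        x[:, a] += delta
                        together[p, a] = new_t
                        together[p, :, a] = new_t

        do_swaps(cfg.burn_in)
        for _ in range(cfg.n_permutations):
            do_swaps(cfg.swaps_per_step)
            yield x * self.inv_d


def preferred_association_test(
    gbi: GroupByIndividual,
    index: str = "SRI",
    config: PermutationConfig | None = None,
    include_zero_dyads: bool = True,
    period_mode: str = "per-period-union",
    conservative: bool = False,
) -> TestResult:
    """Permutation test for preferred/avoided associations via the CV.

    The CV of the observed association indices is compared with the CV of
    each data-stream-randomized version; p is the fraction of randomized
    networks whose CV exceeds the observed one (small p means the observed
    network is more differentiated than random).  The observed and mean null
    CV double as the effect size.
    """
    config = config or PermutationConfig()
    stream = _SwapIndexStream(gbi, config, index=index, period_mode=period_mode)
    n = gbi.n_individuals
    sel = np.triu(np.ones((n, n), bool), k=1)
    if not include_zero_dyads:
        sel &= stream.mask

    def cv_of(weights):
        vals = weights[sel]
        mean = vals.mean()
        if mean <= 0:
            raise ValueError("CV undefined on a replicate: zero mean")
        return float(vals.std(ddof=0) / mean)

    observed = cv_of(stream.observed_weights())
    null = np.array([cv_of(w) for w in stream])
    p = _permutation_pvalue(observed, null, tail="upper", strict=True,
                            conservative=conservative)
    return TestResult(
        statistic_name=f"cv[{index.lower()}]",
        observed=observed,
        null_values=null,
        p_value=p,
        effect_size={"observed_cv": observed, "null_mean_cv": float(null.mean())},
        n_permutations=config.n_permutations,
        config={"index": index, "constraints": list(config.constraints),
                "seed": config.seed, "burn_in": config.burn_in,
                "swaps_per_step": config.swaps_per_step},
    )


# ---------------------------------------------------------------------------
# Permutation-corrected coefficient tests (hierarchical models)
# ---------------------------------------------------------------------------

def parse_formula(formula: str):
    """Parse ``"strength ~ sex + (1|area)"`` into (response, fixed, group)."""
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = (s.strip() for s in formula.split("~", 1))
    fixed, group = [], None
    for term in (t.strip() for t in rhs.split("+")):
        if not term:
            continue
        if term.startswith("(") and term.endswith(")"):
            inner = term[1:-1].replace("¦", "|")
            left, _, grp = inner.partition("|")
            if left.strip() != "1" or not grp.strip():
                raise ValueError(f"only random intercepts '(1|group)' are supported: {term}")
            if group is not None:
                raise ValueError("only one random intercept term is supported")
            group = grp.strip()
        elif term != "1":
            fixed.append(term)
    if not fixed:
        raise ValueError("at least one fixed term is required")
    return lhs, fixed, group


def design_matrix(attributes: AttributeTable, fixed: list[str]):
    """Intercept + dummy-coded design from attribute columns.

    Categorical columns are dummy-coded against their alphabetically first
    level; columns are named ``term[level]``.
    """
    n = len(attributes.registry)
    cols, names = [np.ones(n)], ["Intercept"]
    for term in fixed:
        if term not in attributes.columns:
            raise ValueError(f"attribute column {term!r} does not exist")
        values = attributes.column(term)
        if np.asarray(values).dtype.kind in "fiu":
            cols.append(np.asarray(values, dtype=float))
            names.append(term)
        else:
            levels = sorted(pd.unique(values).tolist())
            for lev in levels[1:]:
                cols.append((np.asarray(values) == lev).astype(float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def _focal_index(names: list[str], fixed: list[str], focal: str | None) -> int:
    target = focal or fixed[0]
    if target in names:
        return names.index(target)
    matches = [k for k, nm in enumerate(names) if nm.split("[")[0] == target]
    if len(matches) != 1:
        raise ValueError(f"cannot resolve focal term {target!r} among {names}")
    return matches[0]


def coefficient_permutation_test(
    gbi: GroupByIndividual,
    attributes: AttributeTable,
    formula: str,
    config: PermutationConfig | None = None,
    *,
    index: str = "SRI",
    metric="strength",
    focal: str | None = None,
    tail: str = "upper",
    period_mode: str = "per-period-union",
    conservative: bool = False,
):
    """Model coefficient with a data-stream permutation p-value.

    Fits ``metric ~ fixed terms (+ one random intercept)`` on the observed
    network, then re-derives the network, the metric and the model for each
    randomized data set, collecting the focal coefficient.  The naive model
    t-statistic is reported alongside the permutation p: with biased sampling
    the former is easily inflated while the latter stays calibrated, because
    the constrained swaps preserve each individual's number of observations.

    Returns ``(TestResult, ModelFit)``.
    """
    config = config or PermutationConfig()
    response, fixed, group = parse_formula(formula)
    X, names = design_matrix(attributes, fixed)
    groups = attributes.column(group) if group else None
    model = RandomInterceptModel(X, groups, terms=names, formula=formula,
                                 group_name=group)
    fidx = _focal_index(names, fixed, focal)

    stream = _SwapIndexStream(gbi, config, index=index, period_mode=period_mode)

    if metric == "strength":
        metric_of = lambda w: w.sum(axis=1)  # noqa: E731
    elif metric == "degree":
        metric_of = lambda w: (w > 0).sum(axis=1).astype(float)  # noqa: E731
    elif callable(metric):
        registry = gbi.registry

        def metric_of(w, _registry=registry, _m=metric):
            return np.asarray(_m(Network(w, _registry, directed=False,
                                         edge_kind="association_index")), dtype=float)
    else:
        raise ValueError("metric must be 'strength', 'degree' or a callable(Network)")

    y_obs = metric_of(stream.observed_weights())
    observed_fit = model.fit(y_obs)
    observed = observed_fit.coefficients[fidx]

    null = np.empty(config.n_permutations)
    failures = 0
    for k, weights in enumerate(stream):
        try:
            null[k] = model.coefficient(metric_of(weights), fidx)
        except Exception:  # noqa: BLE001 - non-convergent replicate dropped
            null[k] = np.nan
            failures += 1
    if failures:
        logger.warning("%d permutation refits failed and were dropped", failures)
    valid = null[~np.isnan(null)]
    p = _permutation_pvalue(observed, valid, tail=tail, conservative=conservative)
    result = TestResult(
        statistic_name=f"coefficient[{names[fidx]}]",
        observed=float(observed),
        null_values=valid,
        p_value=p,
        effect_size={"observed_coefficient": float(observed),
                     "null_mean_coefficient": float(valid.mean()),
                     "naive_t": float(observed_fit.t_statistics[fidx])},
        n_permutations=len(valid),
        config={"formula": formula, "index": index, "metric": str(metric),
                "tail": tail, "constraints": list(config.constraints),
                "seed": config.seed, "burn_in": config.burn_in,
                "swaps_per_step": config.swaps_per_step,
                "dropped_replicates": failures},
    )
    return result, observed_fit


# ---------------------------------------------------------------------------
# Matrix correlation tests
# ---------------------------------------------------------------------------

def _offdiag(m: np.ndarray, directed: bool) -> np.ndarray:
    n = m.shape[0]
    if directed:
        return m[~np.eye(n, dtype=bool)]
    return m[np.triu(np.ones((n, n), bool), k=1)]


def mantel_test(m1: np.ndarray, m2: np.ndarray, n_perm: int = 1000,
                correlation: str = "pearson", tail: str = "two_sided",
                seed: int | None = None, exact: bool = False) -> TestResult:
    """Matrix correlation with node-permutation significance.

    The observed statistic is the (Pearson or Spearman) correlation of the
    corresponding off-diagonal elements; the null simultaneously relabels
    rows and columns of the second matrix.  ``exact=True`` enumerates all
    n! relabelings (small matrices only).
    """
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of identical dimensions")
    n = m1.shape[0]
    directed = not (np.allclose(m1, m1.T) and np.allclose(m2, m2.T))
    corr = (lambda a, b: sps.spearmanr(a, b).statistic) if correlation == "spearman" \
        else (lambda a, b: np.corrcoef(a, b)[0, 1])
    v1 = _offdiag(m1, directed)
    observed = float(corr(v1, _offdiag(m2, directed)))
    if exact:
        from itertools import permutations

        null = np.array([
            corr(v1, _offdiag(m2[np.ix_(p, p)], directed))
            for p in permutations(range(n))
        ])
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            p = rng.permutation(n)
            null[k] = corr(v1, _offdiag(m2[np.ix_(p, p)], directed))
    pval = _permutation_pvalue(observed, null, tail=tail)
    return TestResult(
        statistic_name=f"mantel_r[{correlation}]",
        observed=observed, null_values=null, p_value=pval,
        effect_size={"matrix_correlation": observed},
        n_permutations=len(null),
        config={"tail": tail, "exact": exact, "seed": seed},
    )


def mrqap_dsp(y: np.ndarray, predictors: dict, n_perm: int = 1000,
              seed: int | None = None, tail: str = "two_sided",
              exact: bool = False) -> dict:
    """Multiple regression on dyadic matrices, Dekker double-semi-partialling.

    OLS on the vectorized off-diagonal elements gives the coefficients.  For
    each focal predictor, its residual after regression on the remaining
    predictors is node-relabel-permuted and substituted back; the focal
    coefficient from each permuted design forms the null.  Partial
    correlations are reported as effect sizes.  Returns
    ``{predictor_name: TestResult}``.
    """
    y = np.asarray(y, float)
    names = list(predictors)
    if not names:
        raise ValueError("at least one predictor matrix is required")
    mats = {k: np.asarray(v, float) for k, v in predictors.items()}
    n = y.shape[0]
    directed = not (np.allclose(y, y.T)
                    and all(np.allclose(m, m.T) for m in mats.values()))

    def vec(m):
        return _offdiag(m, directed)

    yv = vec(y)
    Xcols = {k: vec(m) for k, m in mats.items()}
    X = np.column_stack([np.ones_like(yv)] + [Xcols[k] for k in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"exact collinearity among predictors {names}")
    beta_full, *_ = np.linalg.lstsq(X, yv, rcond=None)

    sel = ~np.eye(n, dtype=bool) if directed else np.triu(np.ones((n, n), bool), 1)
    rng = np.random.default_rng(seed)
    results = {}
    for kk, name in enumerate(names):
        others = [names[m] for m in range(len(names)) if m != kk]
        X_other = np.column_stack(
            [np.ones_like(yv)] + [Xcols[o] for o in others]
        )
        # residualize the focal predictor matrix on the other predictors,
        # then put the residuals back into matrix form for node relabeling
        gamma, *_ = np.linalg.lstsq(X_other, Xcols[name], rcond=None)
        resid_v = Xcols[name] - X_other @ gamma
        resid_mat = np.zeros((n, n))
        resid_mat[sel] = resid_v
        if not directed:
            resid_mat = resid_mat + resid_mat.T
        observed = float(beta_full[1 + kk])
        y_resid = yv - X_other @ np.linalg.lstsq(X_other, yv, rcond=None)[0]
        x_resid_v = vec(resid_mat)
        denom = np.linalg.norm(y_resid) * np.linalg.norm(x_resid_v - x_resid_v.mean())
        partial_r = float(
            np.dot(y_resid - y_resid.mean(), x_resid_v - x_resid_v.mean()) / denom
        ) if denom > 0 else 0.0

        def focal_coef(perm):
            pr = resid_mat[np.ix_(perm, perm)]
            Xp = np.column_stack([X_other, vec(pr)])
            b, *_ = np.linalg.lstsq(Xp, yv, rcond=None)
            return b[-1]

        if exact:
            from itertools import permutations

            null = np.array([focal_coef(np.array(p)) for p in permutations(range(n))])
        else:
            null = np.array([focal_coef(rng.permutation(n)) for _ in range(n_perm)])
        pval = _permutation_pvalue(observed, null, tail=tail)
        results[name] = TestResult(
            statistic_name=f"mrqap_beta[{name}]",
            observed=observed, null_values=null, p_value=pval,
            effect_size={"coefficient": observed, "partial_correlation": partial_r},
            n_permutations=len(null),
            config={"tail": tail, "seed": seed, "predictors": names},
        )
    return results


# ---------------------------------------------------------------------------
# Lagged association rates
# ---------------------------------------------------------------------------

@dataclass
class LARCurve:
    """Lagged association rate g(tau): P(together at t + tau | together at t)."""

    lags: np.ndarray
    rates: np.ndarray
    n_pairs: np.ndarray
    null_rate: float

    def __post_init__(self):
        ok = ~np.isnan(self.rates)
        if np.any((self.rates[ok] < 0) | (self.rates[ok] > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def lagged_association_rate(gbi: GroupByIndividual, lag_bins=None) -> LARCurve:
    """Temporal stability of associations at increasing time lags.

    For each lag bin, sums over ordered period pairs (t, t + tau) of the
    number of dyads together at both times, divided by dyads together at t
    whose two members were both identified at t + tau.  Period times come
    from ``row_meta.time`` (first value per period) or default to the period
    sequence index.  The null rate is the expectation under random grouping,
    (mean group size - 1) / (N - 1).
    """
    together, identified = period_cooccurrence(gbi, "per-period-union")
    periods = gbi.periods()
    if len(periods) < 2:
        raise ValueError("lagged association rate requires at least two periods")
    times = []
    for p in periods:
        tvals = gbi.row_meta.loc[gbi.row_meta["period"] == p, "time"]
        tv = tvals.dropna()
        times.append(float(tv.iloc[0]) if len(tv) else np.nan)
    times = np.asarray(times, dtype=float)
    if np.isnan(times).any():
        times = np.arange(len(periods), dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    together = together[order]
    identified = identified[order]

    n_periods = len(periods)
    pair_lags, nums, dens = [], [], []
    triu = np.triu(np.ones(together.shape[1:], dtype=bool), k=1)
    for a in range(n_periods - 1):
        for b in range(a + 1, n_periods):
            lag = times[b] - times[a]
            if lag <= 0:
                continue
            both_ident = identified[b][:, None] & identified[b][None, :]
            num = int((together[a] & together[b] & triu).sum())
            den = int((together[a] & both_ident & triu).sum())
            pair_lags.append(lag)
            nums.append(num)
            dens.append(den)
    pair_lags = np.asarray(pair_lags)
    nums, dens = np.asarray(nums), np.asarray(dens)
    if lag_bins is None:
        lo, hi = pair_lags.min(), pair_lags.max()
        lag_bins = (np.array([lo, hi + 1e-9]) if lo == hi
                    else np.geomspace(lo, hi, 9) * np.array([1] * 8 + [1 + 1e-12]))
    lag_bins = np.asarray(lag_bins, dtype=float)
    which = np.digitize(pair_lags, lag_bins, right=False) - 1
    nbins = len(lag_bins) - 1
    rates = np.full(nbins, np.nan)
    npairs = np.zeros(nbins, dtype=int)
    centers = np.sqrt(lag_bins[:-1] * lag_bins[1:]) if (lag_bins > 0).all() else \
        (lag_bins[:-1] + lag_bins[1:]) / 2
    for k in range(nbins):
        m = which == k
        den = dens[m].sum()
        npairs[k] = den
        if den > 0:
            rates[k] = nums[m].sum() / den
    null_rate = float(np.clip((gbi.group_sizes().mean() - 1) / (gbi.n_individuals - 1), 0, 1))
    return LARCurve(lags=centers, rates=rates, n_pairs=npairs, null_rate=null_rate)


# ---------------------------------------------------------------------------
# Precision: bootstrap and split-half repeatability
# ---------------------------------------------------------------------------

def strength_pipeline(index: str = "SRI", period_mode: str = "per-period-union"):
    """Callable GBI -> per-individual strength under the given index."""

    def pipeline(gbi: GroupByIndividual) -> np.ndarray:
        net = association_index(tally_dyads(gbi, period_mode), index)
        return net.weights.sum(axis=1)

    return pipeline


def bootstrap_metric_ci(gbi: GroupByIndividual, pipeline, n_boot: int = 1000,
                        level: float = 0.95, seed: int | None = None,
                        max_redraws: int = 100):
    """Percentile bootstrap intervals for a node metric.

    Sampling periods are resampled with replacement (each draw counts as a
    distinct unit), the network and metric recomputed per resample.  Returns
    a dict with ``lower``, ``upper`` (registry-aligned arrays), the point
    estimate, and the number of redrawn degenerate resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    periods = gbi.periods()
    codes = pd.Categorical(gbi.row_meta["period"], categories=periods).codes
    rows_by_period = [np.where(codes == k)[0] for k in range(len(periods))]
    point = np.asarray(pipeline(gbi), dtype=float)
    boots = np.empty((n_boot, len(point)))
    redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraws):
            draw = rng.integers(len(periods), size=len(periods))
            rows, labels, times, locs = [], [], [], []
            for rep, pk in enumerate(draw):
                rr = rows_by_period[pk]
                rows.append(gbi.matrix[rr])
                labels.extend([f"{periods[pk]}@{rep}"] * len(rr))
                times.extend(gbi.row_meta["time"].iloc[rr].tolist())
                locs.extend(gbi.row_meta["location"].iloc[rr].tolist())
            meta = pd.DataFrame({"period": labels, "time": times, "location": locs})
            resampled = GroupByIndividual(np.vstack(rows), meta, gbi.registry)
            try:
                boots[b] = np.asarray(pipeline(resampled), dtype=float)
                break
            except Exception:  # noqa: BLE001 - degenerate resample, redraw
                redrawn += 1
        else:
            raise RuntimeError("metric undefined on too many bootstrap resamples")
    alpha = (1 - level) / 2
    return {
        "estimate": point,
        "lower": np.quantile(boots, alpha, axis=0),
        "upper": np.quantile(boots, 1 - alpha, axis=0),
        "level": level,
        "n_redrawn": redrawn,
    }


def split_half_repeatability(gbi: GroupByIndividual, pipeline,
                             split: str = "odd-even") -> float:
    """Spearman correlation of node metrics across two disjoint period halves."""
    periods = gbi.periods()
    if len(periods) < 4:
        raise ValueError("split-half repeatability requires at least 4 periods")
    if split == "odd-even":
        first = set(periods[0::2])
    elif split == "first-second":
        first = set(periods[: len(periods) // 2])
    else:
        raise ValueError("split must be 'odd-even' or 'first-second'")
    in_first = gbi.row_meta["period"].isin(first).to_numpy()
    g1 = gbi.subset_rows(np.where(in_first)[0])
    g2 = gbi.subset_rows(np.where(~in_first)[0])
    v1 = np.asarray(pipeline(g1), dtype=float)
    v2 = np.asarray(pipeline(g2), dtype=float)
    return float(sps.spearmanr(v1, v2).statistic)


# ---------------------------------------------------------------------------
# Sampling effort, social differentiation, and network reliability
# ---------------------------------------------------------------------------

@dataclass
class PowerEstimate:
    """Sampling-power summary: differentiation S, effort H, reliability r.

    ``S`` is the coefficient of variation of the true association indices
    (social differentiation); ``H`` the mean number of identifications
    (joint observations) per dyad; ``r`` the expected correlation between
    the true and the estimated edge weights.
    """

    S: float
    H: float
    r: float

    def __post_init__(self):
        if self.S <= 0 or self.H < 0:
            raise ValueError("require S > 0 and H >= 0")
        if not 0 <= self.r <= 1:
            raise ValueError("r must lie in [0, 1]")


def sampling_correlation(S: float, H: float, n_replicates: int = 200,
                         seed: int | None = None, n_individuals: int = 30,
                         mean_p: float = 0.05) -> PowerEstimate:
    """Simulated true-vs-observed edge correlation at effort H.

    True dyadic association probabilities are gamma distributed with mean
    ``mean_p`` and CV ``S``; each dyad is sampled binomially over enough
    sampling units that the mean identification count per dyad equals ``H``;
    edges are estimated by the simple ratio.  Returns the mean Pearson
    correlation between true and estimated edges over replicates.
    """
    from .synthetic import gamma_association_probabilities

    if S <= 0 or H <= 0:
        raise ValueError("require S > 0 and H > 0")
    rng = np.random.default_rng(seed)
    n_dyads = n_individuals * (n_individuals - 1) // 2
    d = max(int(round(H / mean_p)), 1)
    rs = np.empty(n_replicates)
    for rep in range(n_replicates):
        p = gamma_association_probabilities(n_dyads, S, mean_p, rng)
        x = rng.binomial(d, p)
        est = x / d
        rs[rep] = np.corrcoef(p, est)[0, 1]
    return PowerEstimate(S=S, H=H, r=float(rs.mean()))


def required_sampling_effort(S: float, r_target: float = 0.8) -> float:
    """Identifications per dyad needed for true-observed correlation r_target.

    Closed form H = r^2 / (S^2 (1 - r^2)), the inversion of
    r^2 = S^2 H / (1 + S^2 H); cross-checked against
    :func:`sampling_correlation` in the test suite.  Monotone decreasing in
    S: strongly differentiated societies need far less sampling.
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    if not 0 < r_target < 1:
        raise ValueError("r_target must lie strictly between 0 and 1")
    return float(r_target**2 / (S**2 * (1 - r_target**2)))
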