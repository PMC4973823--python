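import numpy as np
import pandas as pd
import pytest

from asna.association import association_index, tally_dyads
from asna.core import (
    AttributeTable,
    GroupByIndividual,
    IndividualRegistry,
    Network,
)
from asna.nullmodels import PermutationConfig
from asna.stats import (
    _SwapIndexStream,
    bootstrap_metric_ci,
    coefficient_permutation_test,
    lagged_association_rate,
    mantel_test,
    mrqap_dsp,
    network_cv,
    parse_formula,
    preferred_association_test,
    required_sampling_effort,
    sampling_correlation,
    split_half_repeatability,
    strength_pipeline,
)

from conftest import random_gbi


def make_net(weights, ids=None):
    n = weights.shape[0]
    return Network(weights, IndividualRegistry(ids or [str(k) for k in range(n)]),
                   edge_kind="association_index")


class TestNetworkCV:
    def test_equal_indices_zero(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0)
        assert network_cv(make_net(w)) == pytest.approx(0.0)

    def test_half_zero_half_one(self):
        # 4 nodes, 6 dyads: three 0s and three 1s -> sd 0.5 / mean 0.5 = 1
        w = np.zeros((4, 4))
        w[0, 1] = w[0, 2] = w[0, 3] = 1.0
        w = w + w.T
        assert network_cv(make_net(w)) == pytest.approx(1.0)

    def test_mean_preserving_spread_raises_cv(self):
        base = np.full((4, 4), 0.5)
        np.fill_diagonal(base, 0)
        spread = base.copy()
        spread[0, 1] = spread[1, 0] = 0.9
        spread[2, 3] = spread[3, 2] = 0.1
        assert network_cv(make_net(spread)) > network_cv(make_net(base))

    def test_zero_mean_rejected(self):
        w = np.zeros((3, 3))
        with pytest.raises(ValueError, match="mean"):
            network_cv(make_net(w))


def preferred_gbi(rng, n=12, periods=40, boost=10.0):
    """Groups drawn pairwise with half the dyads at boosted probability."""
    ids = [f"i{k}" for k in range(n)]
    registry = IndividualRegistry(ids)
    base = 0.04
    probs = np.full((n, n), base)
    iu, ju = np.triu_indices(n, 1)
    chosen = rng.random(len(iu)) < 0.5
    probs[iu[chosen], ju[chosen]] = base * boost
    rows, meta = [], {"period": [], "time": [], "location": []}
    for p in range(periods):
        hit = rng.random(len(iu)) < probs[iu, ju]
        seen = np.zeros(n, dtype=bool)
        for a, b in zip(iu[hit], ju[hit]):
            row = np.zeros(n, dtype=np.uint8)
            row[[a, b]] = 1
            rows.append(row)
            meta["period"].append(f"P{p}")
            meta["time"].append(float(p))
            meta["location"].append(None)
            seen[[a, b]] = True
        for k in np.where(~seen)[0]:
            row = np.zeros(n, dtype=np.uint8)
            row[k] = 1
            rows.append(row)
            meta["period"].append(f"P{p}")
            meta["time"].append(float(p))
            meta["location"].append(None)
    return GroupByIndividual(np.array(rows), pd.DataFrame(meta), registry)


class TestPreferredAssociationTest:
    def test_detects_planted_preferences(self, rng):
        hits = 0
        for s in range(5):
            gbi = preferred_gbi(np.random.default_rng(s))
            cfg = PermutationConfig(n_permutations=100, burn_in=1000,
                                    swaps_per_step=20, seed=s, constraints=("period",))
            res = preferred_association_test(gbi, "SRI", cfg)
            assert res.observed > res.effect_size["null_mean_cv"]
            hits += res.p_value < 0.05
        assert hits >= 4

    def test_uniform_association_not_flagged(self, rng):
        ps = []
        for s in range(12):
            gbi = preferred_gbi(np.random.default_rng(100 + s), boost=1.0)
            cfg = PermutationConfig(n_permutations=100, burn_in=1000,
                                    swaps_per_step=20, seed=s, constraints=("period",))
            ps.append(preferred_association_test(gbi, "SRI", cfg).p_value)
        # p roughly uniform under the null: not piled near zero
        assert np.mean(ps) > 0.25
        assert sum(p < 0.05 for p in ps) <= 3

    def test_p_rule_proportion(self):
        """p is the share of randomized CVs exceeding the observed CV."""
        from asna.stats import _permutation_pvalue

        null = np.concatenate([np.full(12, 0.9), np.full(988, 0.5)])
        assert _permutation_pvalue(0.8, null, "upper", strict=True) == pytest.approx(0.012)


class TestFormulaAndDesign:
    def test_parse_formula(self):
        resp, fixed, group = parse_formula("strength ~ sex + (1|area)")
        assert (resp, fixed, group) == ("strength", ["sex"], "area")
        resp, fixed, group = parse_formula("deg ~ sex + weight")
        assert group is None and fixed == ["sex", "weight"]

    def test_parse_rejects_slopes(self):
        with pytest.raises(ValueError, match="random intercepts"):
            parse_formula("y ~ x + (x|g)")

    def test_fast_python_path_equals_generic_path(self, rng):
        gbi = random_gbi(rng, n_individuals=8, n_periods=6, n_groups_per_period=3)
        cfg = PermutationConfig(n_permutations=4, burn_in=100, swaps_per_step=7,
                                seed=5, constraints=("period",))
        fast = list(_SwapIndexStream(gbi, cfg, "SRI")._iter_fast_python())
        generic = list(_SwapIndexStream(gbi, cfg, "SRI")._iter_generic())
        for a, b in zip(fast, generic):
            assert np.allclose(a, b)

    def test_numba_kernel_margins_and_tally_exact(self, rng):
        """The jitted chain conserves margins and its incremental tally is exact."""
        pytest.importorskip("numba")
        gbi = random_gbi(rng, n_individuals=10, n_periods=8, n_groups_per_period=3)
        cfg = PermutationConfig(n_permutations=6, burn_in=300, swaps_per_step=50,
                                seed=11, constraints=("period",))
        stream = _SwapIndexStream(gbi, cfg, "SRI")
        last = None
        for w in stream._iter_fast_numba():
            last = w
        # reconstruct x from the emitted SRI weights and the fixed denominator
        d = tally_dyads(gbi).d
        x_emitted = np.round(last * np.where(d > 0, d, 1)).astype(int)
        assert (x_emitted.sum(axis=1) >= 0).all()
        assert np.allclose(last, last.T)


class TestCoefficientPermutationTest:
    def _dataset(self, rng, effect=True):
        from asna.synthetic import box4_dataset, box5_dataset

        seed = int(rng.integers(2**31 - 1))
        return box4_dataset(seed=seed, n_periods=40) if effect else \
            box5_dataset(seed=seed, n_periods=40)

    def test_returns_full_model_fit(self, rng):
        gbi, attrs = self._dataset(rng)
        cfg = PermutationConfig(n_permutations=30, burn_in=300, swaps_per_step=50,
                                seed=0, constraints=("period", "location"))
        res, fit = coefficient_permutation_test(
            gbi, attrs, "strength ~ sex + (1|area)", cfg)
        assert fit.terms == ["Intercept", "sex[male]"]
        assert len(fit.coefficients) == len(fit.standard_errors) == 2
        assert fit.random_effect_name == "area"
        assert 0 <= res.p_value <= 1
        assert res.statistic_name == "coefficient[sex[male]]"

    def test_reproducible_with_seed(self, rng):
        gbi, attrs = self._dataset(rng)
        cfg = PermutationConfig(n_permutations=20, burn_in=200, swaps_per_step=20,
                                seed=42, constraints=("period", "location"))
        r1, _ = coefficient_permutation_test(gbi, attrs, "strength ~ sex + (1|area)", cfg)
        r2, _ = coefficient_permutation_test(gbi, attrs, "strength ~ sex + (1|area)", cfg)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_degree_metric_and_numeric_fixed_term(self, rng):
        gbi, attrs = self._dataset(rng)
        cfg = PermutationConfig(n_permutations=15, burn_in=100, swaps_per_step=20,
                                seed=1, constraints=("period",))
        res, fit = coefficient_permutation_test(
            gbi, attrs, "degree ~ gregariousness", cfg, metric="degree",
            tail="two_sided")
        assert fit.terms == ["Intercept", "gregariousness"]
        assert len(res.null_values) == 15


class TestMantel:
    def _sym(self, rng, n=6):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_self_correlation(self, rng):
        m = self._sym(rng)
        res = mantel_test(m, m, n_perm=200, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_negated_centered(self, rng):
        m = self._sym(rng)
        res = mantel_test(m, -(m - m[np.triu_indices(6, 1)].mean()) + 1.0,
                          n_perm=50, seed=0)
        assert res.observed == pytest.approx(-1.0)

    def test_monte_carlo_matches_exhaustive(self, rng):
        m1, m2 = self._sym(rng, 4), self._sym(rng, 4)
        exact = mantel_test(m1, m2, exact=True)
        mc = mantel_test(m1, m2, n_perm=4000, seed=1)
        assert abs(mc.p_value - exact.p_value) < 0.05
        assert exact.n_permutations == 24

    def test_matches_skbio_statistic(self, rng):
        """Cross-check the matrix correlation itself against scikit-bio."""
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        m1, m2 = self._sym(rng, 7), self._sym(rng, 7)
        r, _, _ = skbio_mantel(DistanceMatrix(m1), DistanceMatrix(m2),
                               permutations=0, method="pearson")
        res = mantel_test(m1, m2, n_perm=10, seed=0)
        assert res.observed == pytest.approx(r, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            mantel_test(self._sym(rng, 4), self._sym(rng, 5))


class TestMRQAP:
    def _sym(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_noiseless_plant(self, rng):
        n = 8
        x1, x2 = self._sym(rng, n), self._sym(rng, n)
        y = 2.0 * x1
        res = mrqap_dsp(y, {"x1": x1, "x2": x2}, n_perm=300, seed=0)
        assert res["x1"].observed == pytest.approx(2.0, abs=1e-10)
        assert res["x2"].observed == pytest.approx(0.0, abs=1e-10)
        assert res["x1"].p_value <= 0.01
        assert res["x2"].p_value > 0.2
        assert res["x1"].effect_size["partial_correlation"] == pytest.approx(1.0)

    def test_single_predictor_decision_agrees_with_mantel(self, rng):
        agree = 0
        for t in range(20):
            n = 7
            x = self._sym(rng, n)
            if t < 10:  # strong signal
                y = x + 0.05 * self._sym(rng, n)
            else:  # pure noise
                y = self._sym(rng, n)
            mq = mrqap_dsp(y, {"x": x}, n_perm=500, seed=t)["x"]
            mt = mantel_test(y, x, n_perm=500, seed=t)
            agree += (mq.p_value < 0.05) == (mt.p_value < 0.05)
        assert agree >= 18

    def test_dsp_p_matches_exhaustive_relabeling(self, rng):
        n = 5
        x = self._sym(rng, n)
        y = x + 0.8 * self._sym(rng, n)
        exact = mrqap_dsp(y, {"x": x}, exact=True)["x"]
        mc = mrqap_dsp(y, {"x": x}, n_perm=3000, seed=2)["x"]
        assert exact.n_permutations == 120
        assert abs(mc.p_value - exact.p_value) < 0.05

    def test_collinear_rejected(self, rng):
        x = self._sym(rng, 6)
        with pytest.raises(ValueError, match="collinearity|collinear"):
            mrqap_dsp(x.copy(), {"a": x, "b": 3 * x}, n_perm=10)


class TestLaggedAssociationRate:
    def _stable_pairs_gbi(self, n=8, periods=10, reshuffle=None, seed=0):
        rng = np.random.default_rng(seed)
        registry = IndividualRegistry([f"i{k}" for k in range(n)])
        pairing = np.arange(n)
        rows, meta = [], {"period": [], "time": [], "location": []}
        for p in range(periods):
            if reshuffle is not None and rng.random() < reshuffle:
                pairing = rng.permutation(n)
            for a in range(0, n, 2):
                row = np.zeros(n, dtype=np.uint8)
                row[[pairing[a], pairing[a + 1]]] = 1
                rows.append(row)
                meta["period"].append(f"P{p}")
                meta["time"].append(float(p))
                meta["location"].append(None)
        return GroupByIndividual(np.array(rows), pd.DataFrame(meta), registry)

    def test_constant_composition_rate_one(self):
        gbi = self._stable_pairs_gbi()
        curve = lagged_association_rate(gbi, lag_bins=np.arange(0.5, 10.5, 1.0))
        assert np.allclose(curve.rates[~np.isnan(curve.rates)], 1.0)

    def test_random_groups_match_combinatorial_baseline(self, rng):
        # independent random groups of size 4 among 12 each period
        n, k, periods = 12, 4, 60
        registry = IndividualRegistry([f"i{j}" for j in range(n)])
        rows, meta = [], {"period": [], "time": [], "location": []}
        for p in range(periods):
            perm = rng.permutation(n)
            for start in range(0, n, k):
                row = np.zeros(n, dtype=np.uint8)
                row[perm[start:start + k]] = 1
                rows.append(row)
                meta["period"].append(f"P{p}")
                meta["time"].append(float(p))
                meta["location"].append(None)
        gbi = GroupByIndividual(np.array(rows), pd.DataFrame(meta), registry)
        curve = lagged_association_rate(gbi, lag_bins=np.array([0.5, 20.5, 59.6]))
        expected = (k - 1) / (n - 1)
        assert curve.null_rate == pytest.approx(expected)
        assert np.allclose(curve.rates, expected, atol=0.05)

    def test_decaying_preference_decays_toward_null(self):
        from scipy.stats import spearmanr

        gbi = self._stable_pairs_gbi(n=12, periods=40, reshuffle=0.25, seed=3)
        curve = lagged_association_rate(gbi, lag_bins=np.array([0.5, 3.5, 10.5, 39.5]))
        rates = curve.rates[~np.isnan(curve.rates)]
        assert rates[0] > rates[-1]
        assert rates[-1] >= curve.null_rate - 0.1
        assert spearmanr(np.arange(len(rates)), rates).statistic < 0

    def test_single_period_rejected(self, rng):
        gbi = random_gbi(rng, n_individuals=5, n_periods=1)
        with pytest.raises(ValueError, match="two periods"):
            lagged_association_rate(gbi)


class TestBootstrapAndSplitHalf:
    def test_degenerate_data_zero_width(self):
        registry = IndividualRegistry(list("abcd"))
        row = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        rows = np.vstack([row] * 10)
        meta = pd.DataFrame({"period": np.repeat([f"P{k}" for k in range(10)], 2)})
        gbi = GroupByIndividual(rows, meta, registry)
        out = bootstrap_metric_ci(gbi, strength_pipeline(), n_boot=100, seed=0)
        assert np.allclose(out["upper"] - out["lower"], 0.0)

    def test_more_periods_tighter_intervals(self):
        def make(periods, seed):
            rng = np.random.default_rng(seed)
            return preferred_gbi(rng, n=8, periods=periods)

        w100 = bootstrap_metric_ci(make(60, 1), strength_pipeline(), n_boot=150,
                                   seed=2)
        w400 = bootstrap_metric_ci(make(240, 1), strength_pipeline(), n_boot=150,
                                   seed=2)
        med100 = np.median(w100["upper"] - w100["lower"])
        med400 = np.median(w400["upper"] - w400["lower"])
        assert med400 < med100

    def test_point_estimate_inside_interval(self, rng):
        gbi = preferred_gbi(rng, n=8, periods=50)
        out = bootstrap_metric_ci(gbi, strength_pipeline(), n_boot=200, seed=3)
        inside = (out["estimate"] >= out["lower"] - 1e-12) & \
                 (out["estimate"] <= out["upper"] + 1e-12)
        assert inside.mean() >= 0.9

    def test_split_half_stable_groups_perfect(self):
        registry = IndividualRegistry(list("abcdef"))
        row1 = np.array([1, 1, 0, 0, 0, 0], dtype=np.uint8)
        row2 = np.array([0, 0, 1, 1, 1, 1], dtype=np.uint8)
        rows = np.vstack([row1, row2] * 8)
        meta = pd.DataFrame({"period": np.repeat([f"P{k}" for k in range(8)], 2)})
        gbi = GroupByIndividual(rows, meta, registry)
        rho = split_half_repeatability(gbi, strength_pipeline())
        assert rho == pytest.approx(1.0)

    def test_split_half_random_regrouping_near_zero(self, rng):
        n, k, periods = 30, 5, 40
        registry = IndividualRegistry([f"i{j}" for j in range(n)])
        rows, meta = [], {"period": []}
        for p in range(periods):
            perm = rng.permutation(n)
            for start in range(0, n, k):
                row = np.zeros(n, dtype=np.uint8)
                row[perm[start:start + k]] = 1
                rows.append(row)
                meta["period"].append(f"P{p}")
        gbi = GroupByIndividual(np.array(rows), pd.DataFrame(meta), registry)
        rho = split_half_repeatability(gbi, strength_pipeline())
        assert abs(rho) < 0.45

    def test_too_few_periods_rejected(self, rng):
        gbi = random_gbi(rng, n_individuals=5, n_periods=3)
        with pytest.raises(ValueError, match="4 periods"):
            split_half_repeatability(gbi, strength_pipeline())


class TestSamplingPower:
    def test_closed_form_triplet(self):
        assert required_sampling_effort(0.2, 0.8) == pytest.approx(44.4, abs=0.1)
        assert required_sampling_effort(0.6, 0.8) == pytest.approx(4.94, abs=0.05)
        assert required_sampling_effort(10.0, 0.8) == pytest.approx(0.0178, abs=0.001)

    def test_monotone_decreasing_in_s(self):
        hs = [required_sampling_effort(s, 0.8) for s in (0.1, 0.3, 1.0, 3.0)]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            required_sampling_effort(0.5, 1.0)
        with pytest.raises(ValueError):
            required_sampling_effort(-1.0, 0.8)

    def test_simulation_matches_closed_form_on_grid(self):
        for S in (0.2, 0.5, 1.0):
            for H in (5.0, 50.0):
                est = sampling_correlation(S, H, n_replicates=150, seed=7,
                                           n_individuals=40)
                expected = np.sqrt(S**2 * H / (1 + S**2 * H))
                assert est.r == pytest.approx(expected, abs=0.03)

    def test_large_effort_limit(self):
        est = sampling_correlation(0.5, 2000.0, n_replicates=30, seed=1)
        assert est.r > 0.98
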