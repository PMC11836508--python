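"""Propensity model, preference scores, matching and balance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

import netcohort as nc

probs = st.floats(0.01, 0.99)
means = st.floats(0.0, 1.0)


def cov_frame(X):
    return pd.DataFrame(X, index=np.arange(len(X)),
                        columns=[f"c{j}" for j in range(X.shape[1])])


class TestComputeSmd:
    @pytest.mark.parametrize("p_t, p_c, expected", [
        (0.793, 0.842, -0.13),   # female, before matching
        (0.842, 0.848, -0.02),   # female, after matching
        (0.494, 0.457, 0.07),    # hypertensive disorder, before
        (0.074, 0.060, 0.06),    # heart failure, before
    ])
    def test_published_prevalence_pairs(self, p_t, p_c, expected):
        assert round(nc.compute_smd(p_t, p_c), 2) == expected

    def test_identical_arms_zero(self):
        assert nc.compute_smd(0.3, 0.3) == 0.0

    @given(means, means, st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    @settings(max_examples=50)
    def test_antisymmetry(self, mt, mc, vt, vc):
        a = nc.compute_smd(mt, mc, vt, vc)
        b = nc.compute_smd(mc, mt, vc, vt)
        assert a == pytest.approx(-b)

    def test_degenerate_cases(self):
        assert nc.compute_smd(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            nc.compute_smd(0.0, 1.0)  # both variances zero, means differ


class TestPreferenceScore:
    @given(probs)
    @settings(max_examples=50)
    def test_identity_at_half_prevalence(self, ps):
        assert nc.preference_score(ps, 0.5) == pytest.approx(ps)

    @given(probs)
    @settings(max_examples=50)
    def test_equal_likelihood_point(self, p):
        assert nc.preference_score(p, p) == pytest.approx(0.5)

    def test_arithmetic_example(self):
        expected = expit(logit(0.8) - logit(0.6))
        assert nc.preference_score(0.8, 0.6) == pytest.approx(expected)
        assert expected == pytest.approx(0.727, abs=5e-4)

    @given(st.tuples(probs, probs), probs)
    @settings(max_examples=50)
    def test_monotone_in_ps(self, pair, prev):
        lo, hi = sorted(pair)
        assume(hi - lo > 1e-9)  # below ~1 ulp the round-trip collapses
        assert (nc.preference_score(lo, prev)
                < nc.preference_score(hi, prev))

    @pytest.mark.parametrize("ps, prev", [(0.0, 0.5), (1.0, 0.5),
                                          (0.5, 0.0), (0.5, 1.0)])
    def test_boundary_errors(self, ps, prev):
        with pytest.raises(ValueError):
            nc.preference_score(ps, prev)


class TestMatching:
    def test_identical_multisets_fully_matched(self):
        ps = np.array([0.2, 0.4, 0.6, 0.8])
        m = nc.match_1to1([0, 1, 2, 3], ps, [10, 11, 12, 13], ps, 0.2)
        assert m.n_pairs == 4
        assert sorted(m.comparator_ids.tolist()) == [10, 11, 12, 13]

    def test_caliper_excludes_separated_arms(self):
        m = nc.match_1to1([0, 1], [0.9, 0.95], [10, 11], [0.05, 0.1], 0.2)
        assert m.n_pairs == 0

    def test_disabled_caliper_matches_min_arm(self):
        m = nc.match_1to1([0, 1], [0.9, 0.95], [10, 11, 12],
                          [0.05, 0.1, 0.2], 0.0)
        assert m.n_pairs == 2
        assert np.isinf(m.caliper)

    def test_greedy_order_documented_example(self):
        """T={0.50,0.60} vs C={0.52,0.70}: greedy processes 0.60 first and
        takes the nearer 0.52, leaving 0.50-0.70; the minimal-total-distance
        pairing (0.60-0.70, 0.50-0.52) differs — greedy is the documented
        behaviour, at the same pair count."""
        m = nc.match_1to1([0, 1], [0.50, 0.60], [10, 11], [0.52, 0.70], 0.0)
        got = dict(zip(m.pairs["target_id"], m.pairs["comparator_id"]))
        assert got == {1: 10, 0: 11}
        # brute-force oracle: same pair count as any maximal matching
        assert m.n_pairs == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_pairing_properties(self, seed):
        """On <=4x4 problems: pair count equals the brute-force maximum
        under the caliper, every pair respects the caliper, and the greedy
        total distance is never better than the optimum (sanity that the
        oracle is a true optimum)."""
        rng = np.random.default_rng(seed)
        nt, ncmp = rng.integers(1, 5, 2)
        t_ps = rng.uniform(0.2, 0.8, nt)
        c_ps = rng.uniform(0.2, 0.8, ncmp)
        cal_mult = 0.5
        m = nc.match_1to1(np.arange(nt), t_ps, 100 + np.arange(ncmp), c_ps,
                          cal_mult)
        lt, lc = logit(t_ps), logit(c_ps)
        sd = np.std(np.concatenate([lt, lc]), ddof=1)
        caliper = cal_mult * sd

        best_count, best_dist = 0, np.inf
        k = min(nt, ncmp)
        for size in range(k, 0, -1):
            for tsub in itertools.combinations(range(nt), size):
                for csub in itertools.permutations(range(ncmp), size):
                    d = [abs(lt[a] - lc[b]) for a, b in zip(tsub, csub)]
                    if max(d) <= caliper + 1e-12:
                        if size > best_count or (size == best_count
                                                 and sum(d) < best_dist):
                            best_count, best_dist = size, sum(d)
            if best_count == size:
                break
        assert m.n_pairs == best_count
        if m.n_pairs:
            got = dict(zip(m.pairs["target_id"],
                           m.pairs["comparator_id"] - 100))
            dist = sum(abs(lt[a] - lc[b]) for a, b in got.items())
            assert all(abs(lt[a] - lc[b]) <= caliper + 1e-12
                       for a, b in got.items())
            assert dist >= best_dist - 1e-12

    def test_pairs_unique_and_arms_equal(self):
        rng = np.random.default_rng(0)
        m = nc.match_1to1(np.arange(500), rng.uniform(0.3, 0.7, 500),
                          1000 + np.arange(700), rng.uniform(0.3, 0.7, 700),
                          0.2)
        assert m.pairs["target_id"].is_unique
        assert m.pairs["comparator_id"].is_unique
        assert len(m.pairs) <= 500

    def test_negative_caliper_errors(self):
        with pytest.raises(ValueError):
            nc.match_1to1([0], [0.5], [1], [0.5], -0.1)


class TestFitPropensity:
    def test_null_model_shrinks_to_noninformative(self):
        rng = np.random.default_rng(1)
        X = (rng.random((10_000, 20)) < 0.3).astype(float)
        y = rng.random(10_000) < 0.4
        cov = cov_frame(X)
        ids = cov.index.to_numpy()
        model = nc.fit_propensity(cov, ids[y], ids[~y], 1.0)
        ps = model.predict(cov)
        assert roc_auc_score(y, ps) <= 0.55

    def test_strong_covariate_sign_recovered(self):
        rng = np.random.default_rng(2)
        X = (rng.random((5000, 5)) < 0.5).astype(float)
        eta = -0.5 + 2.0 * X[:, 3]
        y = rng.random(5000) < expit(eta)
        cov = cov_frame(X)
        ids = cov.index.to_numpy()
        model = nc.fit_propensity(cov, ids[y], ids[~y], 0.5)
        assert model.coefs["c3"] > 0.5
        assert model.prevalence == pytest.approx(y.mean())

    def test_empty_arm_errors(self):
        cov = cov_frame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            nc.fit_propensity(cov, [0, 1, 2, 3], [], 1.0)

    def test_overlapping_arms_error(self):
        cov = cov_frame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            nc.fit_propensity(cov, [0, 1], [1, 2], 1.0)

    def test_separation_without_penalty_errors(self):
        X = np.zeros((40, 1))
        X[:20, 0] = 1.0
        cov = cov_frame(X)
        with pytest.raises(ValueError, match="reg_strength"):
            nc.fit_propensity(cov, np.arange(20), np.arange(20, 40), 0)

    def test_cv_selects_a_positive_strength(self):
        rng = np.random.default_rng(3)
        X = (rng.random((600, 4)) < 0.5).astype(float)
        y = rng.random(600) < expit(-0.3 + X[:, 0])
        cov = cov_frame(X)
        ids = cov.index.to_numpy()
        model = nc.fit_propensity(cov, ids[y], ids[~y], "cv")
        assert model.reg_strength == "cv"
        assert np.isfinite(model.coefs).all()


class TestEquipoiseAndBalance:
    def test_equipoise_trivial_bands(self):
        assert nc.equipoise_fraction([0.5] * 4, [0.5] * 3) == (1.0, 1.0)
        assert nc.equipoise_fraction([0.9] * 4, [0.9] * 3) == (0.0, 0.0)
        assert nc.equipoise_fraction([0.3, 0.7], [0.29, 0.71]) == (1.0, 0.0)

    def test_empty_arm_errors(self):
        with pytest.raises(ValueError):
            nc.equipoise_fraction([], [0.5])

    def test_absent_covariate_zero_smd(self):
        X = np.zeros((6, 2))
        X[:3, 0] = 1
        cov = cov_frame(X)
        m = nc.match_1to1([0, 1, 2], [0.5] * 3, [3, 4, 5], [0.5] * 3, 0.0)
        bal = nc.balance_table(cov, [0, 1, 2], [3, 4, 5], m)
        assert bal.set_index("covariate_id").loc["c1", "smd_after"] == 0.0

    def test_matching_improves_confounder_balance(self, confounded_analysis):
        bal = confounded_analysis.balance
        assert (np.abs(bal["smd_before"]) > np.abs(bal["smd_after"])).mean() > 0.8
        assert np.abs(bal["smd_after"]).max() < 0.1

    def test_randomized_assignment_high_equipoise(self, randomized_analysis):
        eq = randomized_analysis.equipoise
        assert min(eq) > 0.9
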