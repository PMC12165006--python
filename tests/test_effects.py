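"""Policy probabilities, IPW group means, effect contrasts, sandwich SEs."""

import numpy as np
import pytest
from scipy.special import expit

from netspill import (
    AllocationPolicy,
    estimate_effects,
    fit_mixed_logit,
    group_ipw_marginal,
    group_ipw_mean,
    policy_prob,
    policy_prob_excluding,
    population_means,
    sandwich_variance,
)
from netspill.effects import CommunityWeight, community_weights, trim_extreme
from netspill.synthetic import (
    SyntheticStudyConfig,
    generate_study,
    true_community_propensities,
)

from conftest import brute_group_marginal, brute_group_mean


class TestPolicyProbabilities:
    def test_hand_values(self):
        assert policy_prob([1, 0, 0], 0.2) == pytest.approx(0.128, abs=1e-12)
        assert policy_prob([1, 1], 1 - 1e-9) == pytest.approx(1.0, abs=1e-6)
        # 0-based index 1 removes the middle entry of (1, 0, 1)
        assert policy_prob_excluding([1, 0, 1], 1, 0.5) == pytest.approx(0.25)
        assert policy_prob_excluding([1], 0, 0.7) == 1.0  # empty product
        assert policy_prob_excluding([1, 0], 0, 0.2) == pytest.approx(0.8)

    def test_normalization_over_all_vectors(self):
        total = sum(
            policy_prob([(m >> k) & 1 for k in range(3)], 0.3) for m in range(8)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            AllocationPolicy(1.0)


class TestGroupMeans:
    def test_hand_values(self):
        assert group_ipw_mean([1, 0], [1, 1], 0.25, 0.5, arm=1) == pytest.approx(1.0)
        assert group_ipw_mean([1, 0], [1, 1], 0.25, 0.5, arm=0) == pytest.approx(1.0)
        assert group_ipw_mean([1, 0], [0, 0], 0.25, 0.5, arm=1) == 0.0
        assert group_ipw_marginal([1, 0], [1, 1], 0.25, 0.5) == pytest.approx(1.0)
        assert group_ipw_marginal([1], [1], 0.6, 0.6) == pytest.approx(1.0)

    def test_matches_brute_force_loop(self):
        """Vectorized log-space evaluation vs naive enumeration, n_i <= 8."""
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = rng.integers(1, 9)
            a = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            f = rng.uniform(0.01, 1.0)
            alpha = rng.uniform(0.05, 0.95)
            for arm in (0, 1):
                assert group_ipw_mean(a, y, f, alpha, arm) == pytest.approx(
                    brute_group_mean(list(a), list(y), f, alpha, arm), abs=1e-12
                )
            assert group_ipw_marginal(a, y, f, alpha) == pytest.approx(
                brute_group_marginal(list(a), list(y), f, alpha), abs=1e-12
            )

    def test_population_mean(self):
        assert population_means([0.2, 0.4]) == pytest.approx(0.3)
        assert population_means([0.7]) == 0.7


class TestWeights:
    def test_weight_one_when_policy_matches_propensity(self):
        a = {1: np.array([1.0, 0.0])}
        f = {1: 0.25}
        (w,) = community_weights(a, f, 0.5)
        assert w.weight == pytest.approx(1.0)
        assert trim_extreme([w]) == {1}

    def test_trim_thresholds(self):
        ws = [CommunityWeight(1, 0.2, 5e-4), CommunityWeight(2, 0.2, 0.8),
              CommunityWeight(3, 0.2, 9.0)]
        assert trim_extreme(ws, low=0.001) == {2, 3}
        assert trim_extreme(ws, low=0.001, high=8.0) == {2}


@pytest.fixture(scope="module")
def small_study():
    cfg = SyntheticStudyConfig(
        seed=42, n_communities=40, size_log_mean=np.log(6.0), size_log_sd=0.4,
        outcome_missing_rate=0.0,
    )
    study = generate_study(cfg)
    model = fit_mixed_logit(study.records, study.true_structure, ["risk_base", "age"])
    return study, model


class TestEstimateEffects:
    def test_total_equals_direct_plus_spillover(self, small_study):
        study, model = small_study
        res = estimate_effects(study.network, study.true_structure, model)
        for al, al_p in [(0.6, 0.2), (0.4, 0.2), (0.6, 0.4)]:
            de = res.effect("direct", al).estimate
            se = res.effect("spillover", al, al_p).estimate
            te = res.effect("total", al, al_p).estimate
            assert te == pytest.approx(de + se, abs=1e-12)

    def test_invalid_pair_rejected(self, small_study):
        study, model = small_study
        with pytest.raises(ValueError, match="alpha > alpha_prime"):
            estimate_effects(study.network, study.true_structure, model,
                             alpha_pairs=[(0.2, 0.6)])
        with pytest.raises(ValueError, match="alpha > alpha_prime"):
            estimate_effects(study.network, study.true_structure, model,
                             alpha_pairs=[(0.4, 0.4)])

    def test_wald_interval_geometry(self, small_study):
        study, model = small_study
        res = estimate_effects(study.network, study.true_structure, model)
        for e in res.estimates:
            assert e.ci_low == pytest.approx(e.estimate - 1.96 * e.se)
            assert e.ci_high == pytest.approx(e.estimate + 1.96 * e.se)

    def test_no_op_trim_leaves_estimates_unchanged(self, small_study):
        study, model = small_study
        res = estimate_effects(study.network, study.true_structure, model)
        retained = trim_extreme(res.weights, low=1e-12)
        assert retained == {w.community for w in res.weights}
        res2 = estimate_effects(study.network, study.true_structure, model,
                                exclude_communities=set())
        assert res2.effect("direct", 0.2).estimate == res.effect("direct", 0.2).estimate

    def test_known_propensity_se_is_clt_form(self, small_study):
        """With a known (not estimated) f, the sandwich must reduce to the
        i.i.d. per-community CLT standard error SD/sqrt(N)."""
        study, _ = small_study
        truef = true_community_propensities(study)
        res = estimate_effects(study.network, study.true_structure, None,
                               known_propensity=truef, alphas=[0.4],
                               alpha_pairs=[(0.6, 0.2)])
        from netspill.effects import group_ipw_mean as gim

        comms = study.true_structure.communities()
        vals = []
        for lab in sorted(l for l, m in comms.items() if len(m) > 1):
            members = sorted(comms[lab])
            a = [study.network.records[m].treatment for m in members]
            y = [study.network.records[m].outcome for m in members]
            vals.append(gim(a, y, truef[lab], 0.4, arm=1))
        vals = np.array(vals)
        expected_se = vals.std(ddof=0) / np.sqrt(len(vals))
        cov = res.mean_cov
        # target order: (1, a), (0, a), (marg, a) per sorted alpha; 0.4 is 2nd
        se_arm1_04 = np.sqrt(cov[3, 3])
        assert se_arm1_04 == pytest.approx(expected_se, abs=1e-8)

    def test_singletons_excluded(self):
        cfg = SyntheticStudyConfig(
            seed=9, sizes=[1, 4, 5, 6, 4, 5], outcome_missing_rate=0.0
        )
        study = generate_study(cfg)
        model = fit_mixed_logit(study.records, study.true_structure,
                                ["risk_base", "age"])
        res = estimate_effects(study.network, study.true_structure, model)
        assert res.n_singletons_excluded == 1
        assert res.n_communities == 5

    def test_missing_outcomes_rejected(self):
        study = generate_study(SyntheticStudyConfig(seed=10, n_communities=10))
        model_recs = [r.replace(outcome=0) for r in study.records]
        model = fit_mixed_logit(model_recs, study.true_structure,
                                ["risk_base", "age"])
        with pytest.raises(ValueError, match="impute"):
            estimate_effects(study.network, study.true_structure, model)


class TestSandwich:
    def test_known_propensity_reduces_to_empirical_covariance(self):
        rng = np.random.default_rng(1)
        psi = rng.normal(size=(50, 3))
        psi -= psi.mean(axis=0)
        cov = sandwich_variance(psi)
        assert np.allclose(cov, psi.T @ psi / 50**2, atol=1e-14)

    def test_needs_two_communities(self):
        with pytest.raises(ValueError, match="at least 2"):
            sandwich_variance(np.zeros((1, 2)))

    def test_singular_bread_detected(self):
        psi = np.random.default_rng(2).normal(size=(30, 2))
        scores = np.zeros((30, 1))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            sandwich_variance(psi, scores=scores, bread_cross=np.zeros((2, 1)),
                              hessian=np.zeros((1, 1)))

    def test_agrees_with_community_bootstrap(self):
        """Sandwich SEs (estimated propensity) vs a 300-resample community
        bootstrap on one fixed synthetic dataset: within 20% relative."""
        cfg = SyntheticStudyConfig(
            seed=77, n_communities=60, size_log_mean=np.log(5.0), size_log_sd=0.35,
            outcome_missing_rate=0.0,
        )
        study = generate_study(cfg)
        st = study.true_structure
        model = fit_mixed_logit(study.records, st, ["risk_base", "age"])
        res = estimate_effects(study.network, st, model, alphas=[0.5],
                               alpha_pairs=[(0.6, 0.2)])
        boot = _bootstrap_ses(study, ["risk_base", "age"],
                              n_boot=300, seed=123,
                              start=(model.theta, model.sigma_b))
        for key in ["direct", "spillover"]:
            if key == "direct":
                ours = res.effect("direct", 0.5).se
            else:
                ours = res.effect("spillover", 0.6, 0.2).se
            assert abs(ours - boot[key]) / boot[key] < 0.2


def _bootstrap_ses(study, spec, n_boot, seed, start=None):
    """Community-resampling bootstrap of DE(0.5) and SE(0.6, 0.2)."""
    from netspill import CommunityStructure
    from netspill.network import RiskNetwork

    rng = np.random.default_rng(seed)
    comms = study.true_structure.communities()
    labels = sorted(l for l, m in comms.items() if len(m) > 1)
    de, se = [], []
    for _ in range(n_boot):
        chosen = rng.choice(labels, size=len(labels), replace=True)
        records, assignment = {}, {}
        edges = []
        for new_lab, lab in enumerate(chosen, start=1):
            for node in comms[lab]:
                rec = study.network.records[node]
                nid = f"b{new_lab}_{node}"
                records[nid] = rec.replace(id=nid)
                assignment[nid] = new_lab
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(records)
        net = RiskNetwork(graph=g, records=records)
        st = CommunityStructure(assignment)
        try:
            model = fit_mixed_logit(list(records.values()), st, spec, start=start)
            res = estimate_effects(net, st, model, alphas=[0.5],
                                   alpha_pairs=[(0.6, 0.2)], compute_se=False)
        except Exception:
            continue
        de.append(res.effect("direct", 0.5).estimate)
        se.append(res.effect("spillover", 0.6, 0.2).estimate)
    return {"direct": float(np.std(de, ddof=1)), "spillover": float(np.std(se, ddof=1))}
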