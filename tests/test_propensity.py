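"""Mixed-logit propensity model, community propensity scores, screening."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from netspill import (
    CommunityStructure,
    ParticipantRecord,
    community_propensity,
    fit_mixed_logit,
    screen_covariates,
)
from netspill.propensity import (
    PropensityModel,
    SeparationError,
    _GroupedData,
    build_design,
    community_loglik,
)


def _model(theta, sigma, spec=("x",), columns=None):
    theta = np.asarray(theta, float)
    return PropensityModel(
        covariate_spec=list(spec), columns=columns or ["(intercept)", *spec],
        coding={}, theta=theta, sigma_b=sigma, loglik=0.0, converged=True,
    )


def _recs_from(xs, a):
    return [
        ParticipantRecord(f"p{i}", int(ai), 0, {"x": float(xi)})
        for i, (xi, ai) in enumerate(zip(xs, a))
    ]


class TestCommunityPropensity:
    def test_degenerate_random_effect_is_plain_product(self):
        # sigma = 0, linear predictors 0 => each member contributes 0.5
        model = _model([0.0, 0.0], 0.0)
        cp = community_propensity(model, _recs_from([0, 0], [1, 0]))
        assert cp.f_value == pytest.approx(0.25, abs=1e-12)

    def test_product_rule_with_heterogeneous_h(self):
        # h = (0.9, 0.8), both treated -> f = 0.72
        xs = [logit(0.9), logit(0.8)]
        model = _model([0.0, 1.0], 0.0)
        cp = community_propensity(model, _recs_from(xs, [1, 1]))
        assert cp.f_value == pytest.approx(0.72, abs=1e-10)

    def test_single_member_symmetric_random_effect(self):
        # E[expit(b)] = 0.5 for b ~ N(0, 1) by symmetry
        model = _model([0.0, 0.0], 1.0)
        cp = community_propensity(model, _recs_from([0.0], [1]))
        assert cp.f_value == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("sigma", [0.0, 0.6, 1.3])
    def test_law_of_total_probability(self, sigma):
        """Sum of f over all 2^n treatment vectors is exactly 1."""
        rng = np.random.default_rng(8)
        n = 7
        x = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        theta = np.array([-0.4, 0.9])
        total = 0.0
        for bits in itertools.product([0.0, 1.0], repeat=n):
            data = _GroupedData(x, np.array(bits), np.zeros(n, int), 1, [1])
            total += float(np.exp(community_loglik(theta, sigma, data))[0])
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_quadrature_node_stability(self):
        rng = np.random.default_rng(9)
        n = 30
        x = np.column_stack([np.ones(n), rng.uniform(-2, 2, n)])
        theta = np.array([0.5, 1.5])  # |linear predictor| <= 3.5
        y = (rng.random(n) < 0.4).astype(float)
        data = _GroupedData(x, y, np.zeros(n, int), 1, [1])
        f21 = np.exp(community_loglik(theta, 1.0, data, 21))
        f41 = np.exp(community_loglik(theta, 1.0, data, 41))
        assert abs(f21 - f41) / f41 < 1e-6

    def test_longer_vector_never_more_probable(self):
        model = _model([0.2, 0.5], 0.7)
        short = community_propensity(model, _recs_from([0.3, -1.0], [1, 0]))
        longer = community_propensity(
            model, _recs_from([0.3, -1.0, 0.8], [1, 0, 1])
        )
        assert longer.f_value <= short.f_value


class TestFit:
    def test_intercept_only_matches_closed_form(self):
        rng = np.random.default_rng(5)
        recs, assign = [], {}
        for i in range(400):
            for j in range(5):
                pid = f"c{i}_{j}"
                recs.append(ParticipantRecord(pid, int(rng.random() < 0.4), 0, {}))
                assign[pid] = i + 1
        m = fit_mixed_logit(recs, CommunityStructure(assign), [])
        frac = np.mean([r.treatment for r in recs])
        assert m.theta[0] == pytest.approx(logit(frac), abs=0.05)
        assert m.sigma_b < 0.2  # no true heterogeneity

    def test_sigma_boundary_when_no_heterogeneity(self):
        rng = np.random.default_rng(6)
        recs, assign = [], {}
        for i in range(300):
            for j in range(6):
                pid = f"c{i}_{j}"
                x = rng.normal()
                recs.append(ParticipantRecord(
                    pid, int(rng.random() < expit(-0.5 + x)), 0, {"x": x}))
                assign[pid] = i + 1
        m = fit_mixed_logit(recs, CommunityStructure(assign), ["x"])
        assert m.sigma_b < 0.15

    def test_parameter_recovery_within_sampling_error(self):
        """theta=(−1, 1.2), sigma_b=0.8 on 300 communities of 5."""
        rng = np.random.default_rng(7)
        recs, assign = [], {}
        for i in range(300):
            b = rng.normal(0, 0.8)
            for j in range(5):
                pid = f"c{i}_{j}"
                x = rng.normal()
                recs.append(ParticipantRecord(
                    pid, int(rng.random() < expit(-1 + 1.2 * x + b)), 0, {"x": x}))
                assign[pid] = i + 1
        m = fit_mixed_logit(recs, CommunityStructure(assign), ["x"])
        # 3x the approximate sampling SDs seen across replicates of this size
        assert m.theta[0] == pytest.approx(-1.0, abs=0.45)
        assert m.theta[1] == pytest.approx(1.2, abs=0.45)
        assert m.sigma_b == pytest.approx(0.8, abs=0.75)

    def test_constant_treatment_rejected(self):
        recs = [ParticipantRecord(f"p{i}", 1, 0, {}) for i in range(10)]
        st = CommunityStructure({r.id: 1 + i % 2 for i, r in enumerate(recs)})
        with pytest.raises(ValueError, match="constant"):
            fit_mixed_logit(recs, st, [])

    def test_separation_names_column(self):
        recs = [
            ParticipantRecord(f"p{i}", int(i < 5), 0, {"x": float(i < 5)})
            for i in range(10)
        ]
        st = CommunityStructure({r.id: 1 + i % 3 for i, r in enumerate(recs)})
        with pytest.raises(SeparationError, match="x"):
            fit_mixed_logit(recs, st, ["x"])


class TestDesignAndScreening:
    def test_reference_coding_sorted_levels(self):
        import pandas as pd

        df = pd.DataFrame({"g": ["b", "a", "c", "a"], "z": [1.0, 2.0, 3.0, 4.0]})
        x, names, coding = build_design(df, ["g", "z"])
        assert coding["g"] == ["a", "b", "c"]
        assert names == ["(intercept)", "g[b]", "g[c]", "z"]
        assert x[:, 1].tolist() == [1.0, 0.0, 0.0, 0.0]

    def _records(self, n=300, seed=0, dup=False):
        # u, v cycle through all four combinations: exactly independent
        # (chi-square p = 1 by construction)
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            u, v = (i >> 1) & 1, i & 1
            covs = {"u": str(u), "v": str(v)}
            if dup:
                covs["u_copy"] = str(u)
            recs.append(ParticipantRecord(
                f"p{i}", int(rng.random() < expit(-1 + u)), 0, covs))
        return recs

    def test_independent_covariates_retained(self):
        recs = self._records()
        kept, report = screen_covariates(recs, ["u", "v"], check_fit=False)
        assert kept == ["u", "v"]
        assert report == []

    def test_duplicated_covariate_dropped(self):
        recs = self._records(dup=True)
        kept, report = screen_covariates(recs, ["u", "u_copy", "v"], check_fit=False)
        assert "u" in kept  # later duplicate loses the tie
        assert "u_copy" not in kept
        assert len(report) == 1

    def test_perfectly_associated_pair_dropped_at_stage2(self):
        # w is a noisy (not collinear) but strongly associated copy of u
        recs = self._records()
        for i, r in enumerate(recs):
            u = int(r.covariates["u"])
            r.covariates["w"] = str(u if i % 11 else 1 - u)
        kept, report = screen_covariates(recs, ["u", "w", "v"], check_fit=False)
        assert kept == ["u", "v"]
        assert report[0]["stage"] == 2 and report[0]["covariate"] == "w"

    def test_perfectly_collinear_numeric_dropped_by_vif(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(200):
            z = rng.normal()
            recs.append(ParticipantRecord(
                f"p{i}", int(rng.random() < 0.3), 0,
                {"z1": z, "z2": 2.0 * z + rng.normal(0, 1e-3), "w": rng.normal()}))
        kept, report = screen_covariates(recs, ["z1", "z2", "w"], check_fit=False)
        assert "w" in kept
        assert sum(r["stage"] == 1 for r in report) >= 1

    def test_all_eliminated_errors(self):
        recs = self._records(dup=True)
        with pytest.raises(ValueError, match="at least two"):
            screen_covariates(recs, ["u"], check_fit=False)
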